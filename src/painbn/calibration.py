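"""Published reference statistics used to calibrate the default cohort generator.

These constants describe the survey cohort the generator emulates: marginal
prevalence counts per body region, the demographic composition, the arc set of
the reported pain network, and the published pairwise conditional percentages,
odds ratios, and 95% CI bounds for each arc. They are treated as empirical
calibration targets, not as fitted model output.
"""

from __future__ import annotations

from .model import DEMOGRAPHIC, PAIN, PAIN_LEVELS, VariableSpec

COHORT_N = 2400
GENDER_SPLIT = 0.50  # proportion female
AGE_MIX = (0.409, 0.506, 0.085)  # young, middle, senior

AGE_LEVELS = ("young", "middle", "senior")
GENDER_LEVELS = ("female", "male")

#: Pain indicators in published body-region order.
PAIN_VARIABLES = (
    "headache",
    "all_body",
    "face",
    "neck",
    "back",
    "stomach",
    "hip",
    "knee",
    "hand",
    "foot",
)

#: (yes count, no count) per body region out of COHORT_N participants.
PREVALENCE_COUNTS = {
    "headache": (747, 1653),
    "all_body": (146, 2254),
    "face": (69, 2331),
    "neck": (824, 1576),
    "back": (836, 1564),
    "stomach": (523, 1877),
    "hip": (160, 2240),
    "knee": (597, 1803),
    "hand": (214, 2186),
    "foot": (301, 2099),
}

#: Arc set of the reported network (parent, child).
TRUTH_ARCS = (
    ("age", "headache"),
    ("age", "knee"),
    ("gender", "headache"),
    ("gender", "hand"),
    ("gender", "neck"),
    ("headache", "neck"),
    ("headache", "hip"),
    ("headache", "stomach"),
    ("headache", "face"),
    ("headache", "back"),
    ("hip", "hand"),
    ("hand", "face"),
    ("hand", "foot"),
    ("hand", "all_body"),
    ("hand", "back"),
    ("hand", "neck"),
    ("neck", "back"),
    ("neck", "foot"),
    ("neck", "stomach"),
    ("back", "stomach"),
    ("back", "knee"),
    ("back", "all_body"),
    ("foot", "knee"),
)

#: Published pairwise association rows:
#: (parent, parent_level, child, yes_pct, no_pct, odds_ratio, ci_lower, ci_upper)
#: where yes_pct = 100 * P(child=yes | parent at parent_level) and
#: no_pct = 100 * P(child=yes | parent NOT at parent_level) (level-vs-rest).
RELATIONSHIP_TARGETS = (
    ("age", "young", "headache", 39.450, 25.370, 1.917, 1.609, 2.284),
    ("age", "middle", "headache", 27.737, 34.599, 0.726, 0.610, 0.863),
    ("age", "senior", "headache", 11.275, 32.969, 0.258, 0.166, 0.402),
    ("age", "young", "knee", 17.839, 29.739, 0.513, 0.420, 0.626),
    ("age", "middle", "knee", 27.901, 21.772, 1.390, 1.154, 1.675),
    ("age", "senior", "knee", 40.686, 23.406, 2.245, 1.669, 3.019),
    ("gender", "female", "headache", 37.833, 24.417, 1.884, 1.580, 2.246),
    ("gender", "female", "hand", 12.500, 5.333, 2.536, 1.870, 3.438),
    ("gender", "female", "neck", 41.667, 27.000, 1.931, 1.627, 2.293),
    ("headache", "yes", "neck", 51.138, 26.739, 2.867, 2.395, 3.433),
    ("headache", "yes", "hip", 10.442, 4.961, 2.234, 1.617, 3.085),
    ("headache", "yes", "stomach", 35.475, 15.608, 2.973, 2.433, 3.632),
    ("headache", "yes", "face", 7.631, 0.726, 11.297, 6.024, 21.186),
    ("headache", "yes", "back", 50.067, 27.949, 2.585, 2.161, 3.092),
    ("hip", "yes", "hand", 38.750, 6.786, 8.691, 6.074, 12.434),
    ("hand", "yes", "face", 13.551, 1.830, 8.410, 5.096, 13.880),
    ("hand", "yes", "foot", 45.794, 9.286, 8.253, 6.082, 11.199),
    ("hand", "yes", "all_body", 25.234, 4.209, 7.682, 5.293, 11.149),
    ("hand", "yes", "back", 65.421, 31.839, 4.050, 3.013, 5.444),
    ("hand", "yes", "neck", 66.822, 31.153, 4.451, 3.302, 6.000),
    ("neck", "yes", "back", 56.675, 23.414, 4.279, 3.572, 5.125),
    ("neck", "yes", "foot", 23.301, 6.916, 4.089, 3.175, 5.265),
    ("neck", "yes", "stomach", 34.830, 14.975, 3.035, 2.486, 3.704),
    ("back", "yes", "stomach", 33.493, 15.537, 2.738, 2.245, 3.338),
    ("back", "yes", "knee", 40.311, 16.624, 3.387, 2.796, 4.104),
    ("back", "yes", "all_body", 11.842, 3.005, 4.336, 3.030, 6.203),
    ("foot", "yes", "knee", 55.150, 20.534, 4.759, 3.704, 6.114),
)

#: Worked-example probabilities: P(neck=yes | headache=yes) and | headache=no.
WORKED_EXAMPLE = (0.51138, 0.26739)


def default_schema() -> list[VariableSpec]:
    """Demographics first, then the ten binary pain indicators."""
    schema = [
        VariableSpec("age", AGE_LEVELS, DEMOGRAPHIC),
        VariableSpec("gender", GENDER_LEVELS, DEMOGRAPHIC),
    ]
    schema += [VariableSpec(name, PAIN_LEVELS, PAIN) for name in PAIN_VARIABLES]
    return schema


def prevalence(name: str) -> float:
    """Marginal P(yes) for a pain variable from the published counts."""
    yes, no = PREVALENCE_COUNTS[name]
    return yes / (yes + no)
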