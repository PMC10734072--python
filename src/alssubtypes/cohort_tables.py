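"""Published cluster demographics of four ALS expression cohorts.

Observed counts from the reported three-cluster composition of four
case-only ALS cohorts — a UK motor-cortex brain-bank cohort (KCL
BrainBank), a US motor-cortex cohort (TargetALS), and two peripheral-blood
cohorts (Zucca; van Rheenen) — as printed in the study's demographic
table. These counts are the inputs to the chi-square tests of
subtype-phenotype association; entries are numbers of individuals.

Each binary category is stored as (counts per cluster, cluster totals);
the van Rheenen onset-site comparison is the direct limb-vs-bulbar 2x3
table because combined limb-and-bulbar onset was not recorded there.
"""

CLUSTER_SIZES = {
    "kcl": (60, 28, 24),
    "targetals": (97, 28, 43),
    "zucca": (13, 1, 1),
    "van_rheenen": (335, 33, 29),
}

# category -> {cohort: per-cluster positive counts}
BINARY_COUNTS = {
    "male": {
        "kcl": (35, 15, 15),
        "targetals": (60, 18, 21),
        "zucca": (6, 0, 1),
        "van_rheenen": (205, 18, 16),
    },
    "c9_positive": {
        "kcl": (7, 1, 0),
        "targetals": (11, 0, 4),
    },
    "limb_onset": {
        "kcl": (36, 10, 17),
        "targetals": (65, 22, 17),
    },
    "bulbar_onset": {
        "kcl": (15, 7, 5),
        "targetals": (14, 5, 21),
    },
    "limb_and_bulbar_onset": {
        "kcl": (1, 1, 0),
        "targetals": (7, 0, 1),
    },
}

# van Rheenen site of onset: limb vs bulbar across the three clusters
VAN_RHEENEN_ONSET = {
    "limb": (215, 21, 15),
    "bulbar": (120, 12, 14),
}
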