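"""Published summary statistics of the longitudinal autism cohort emulated here.

These are the demographic marginals of the reference study sample (161
autistic participants stratified into 53 Decreasers / 42 No-changers /
66 Increasers, and 172 neurotypicals, aged 6-30, two visits ~1.6 years
apart).  They serve two roles: as default targets for the synthetic-cohort
generator, and as inputs for reproducing the summary-statistic tests
(one-way ANOVA F from printed mean/SD/n, Pearson chi-square from printed
counts) that characterise the cohort.
"""

# (mean, sd) of the VABS-II composite change per outcome subgroup
DELTA_V_STANDARD = {
    "Decreaser": (-11.23, 8.0),
    "No-changer": (0.05, 2.0),
    "Increaser": (9.86, 5.5),
}

# (mean, sd) of VABS-II domain change per subgroup, for domain stratification
DELTA_V_DOMAINS = {
    "comm": {
        "Decreaser": (-15.06, 13.1),
        "No-changer": (-2.55, 6.8),
        "Increaser": (9.15, 13.0),
    },
    "daily": {
        "Decreaser": (-10.40, 8.5),
        "No-changer": (0.14, 7.4),
        "Increaser": (8.59, 8.7),
    },
    "social": {
        "Decreaser": (-7.83, 9.9),
        "No-changer": (2.45, 7.8),
        "Increaser": (12.36, 10.1),
    },
}

SUBGROUP_NS = {"Decreaser": 53, "No-changer": 42, "Increaser": 66}
N_AUTISTIC = 161
N_NEUROTYPICAL = 172

FSIQ = {"autistic": (101.82, 19.8), "neurotypical": (107.05, 16.5)}
FSIQ_SUBGROUPS = {
    "Decreaser": (95.75, 18.9),
    "No-changer": (105.06, 22.6),
    "Increaser": (104.63, 17.8),
}

# females, males
SEX_COUNTS_DIAGNOSIS = {"autistic": (50, 111), "neurotypical": (64, 108)}
SEX_COUNTS_SUBGROUPS = {
    "Decreaser": (25, 28),
    "No-changer": (6, 36),
    "Increaser": (19, 47),
}

AGE_YEARS = {"autistic": (16.87, 5.5), "neurotypical": (16.35, 5.7)}
INTERVISIT_YEARS = {"autistic": (1.62, 0.3), "neurotypical": (1.59, 0.3)}

VABS_STANDARD_T1 = (72.50, 12.5)
VABS_STANDARD_T2_SUBGROUPS = {
    "Decreaser": (64.38, 18.7),
    "No-changer": (73.36, 10.8),
    "Increaser": (79.36, 11.0),
}
DELTA_V_SOCIAL_SUBGROUPS = DELTA_V_DOMAINS["social"]

TOTAL_SA_CM2 = {"autistic": (2293.40, 232.0), "neurotypical": (2316.47, 225.0)}
TOTAL_SA_CM2_SUBGROUPS = {
    "Decreaser": (2230.11, 271.08),
    "No-changer": (2349.98, 159.96),
    "Increaser": (2308.22, 228.0),
}
MEAN_CT_MM = {"autistic": (2.69, 0.1), "neurotypical": (2.69, 0.1)}

ADOS_CSS_T1 = {"total": (5.20, 2.74), "sa": (5.86, 2.7), "rrb": (4.54, 2.8)}
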