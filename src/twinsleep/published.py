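"""Published multivariate AE estimates for the seven components in
middle-aged adults: per-trait heritabilities, pairwise etiological and
phenotypic correlations, and the reported A-shares of each phenotypic
correlation.

These serve two roles: the worked example of the bivariate decomposition
(the printed shares are reproducible from the printed heritabilities and
correlations), and the ground truth of the synthetic reference cohort.
"""

from __future__ import annotations

#: per-trait standardized additive-genetic variance (h2)
H2 = {
    "latency": 0.23, "duration": 0.25, "efficiency": 0.21, "disturbances": 0.32,
    "sleep_quality": 0.30, "medication": 0.40, "daytime_dysfunction": 0.36,
}

#: (rA, rE, rPH) per unordered trait pair
CORRELATIONS = {
    ("duration", "latency"): (-0.45, -0.27, -0.31),
    ("efficiency", "latency"): (-0.42, -0.36, -0.38),
    ("efficiency", "duration"): (0.69, 0.63, 0.64),
    ("disturbances", "latency"): (0.36, 0.32, 0.33),
    ("disturbances", "duration"): (-0.35, -0.30, -0.31),
    ("disturbances", "efficiency"): (-0.39, -0.36, -0.36),
    ("sleep_quality", "latency"): (0.74, 0.36, 0.46),
    ("sleep_quality", "duration"): (-0.66, -0.41, -0.48),
    ("sleep_quality", "efficiency"): (-0.65, -0.41, -0.47),
    ("sleep_quality", "disturbances"): (0.69, 0.43, 0.51),
    ("medication", "latency"): (0.48, 0.18, 0.27),
    ("medication", "duration"): (-0.26, 0.03, -0.06),
    ("medication", "efficiency"): (-0.30, -0.17, -0.21),
    ("medication", "disturbances"): (0.50, 0.10, 0.24),
    ("medication", "sleep_quality"): (0.55, 0.31, 0.39),
    ("daytime_dysfunction", "latency"): (0.44, 0.03, 0.15),
    ("daytime_dysfunction", "duration"): (-0.17, -0.22, -0.21),
    ("daytime_dysfunction", "efficiency"): (-0.25, -0.16, -0.18),
    ("daytime_dysfunction", "disturbances"): (0.49, 0.23, 0.32),
    ("daytime_dysfunction", "sleep_quality"): (0.44, 0.34, 0.37),
    ("daytime_dysfunction", "medication"): (0.33, 0.19, 0.25),
}

#: reported A-share of each phenotypic correlation (below-diagonal cells);
#: the medication-duration pair is excluded: its contributions have
#: opposite signs and are reported as signed values (A_SHARE_SIGNED)
A_SHARE = {
    ("duration", "latency"): 0.34,
    ("efficiency", "latency"): 0.24,
    ("efficiency", "duration"): 0.25,
    ("disturbances", "latency"): 0.30,
    ("disturbances", "duration"): 0.32,
    ("disturbances", "efficiency"): 0.28,
    ("sleep_quality", "latency"): 0.42,
    ("sleep_quality", "duration"): 0.38,
    ("sleep_quality", "efficiency"): 0.35,
    ("sleep_quality", "disturbances"): 0.42,
    ("medication", "latency"): 0.54,
    ("medication", "disturbances"): 0.74,
    ("medication", "sleep_quality"): 0.49,
    ("daytime_dysfunction", "latency"): 0.84,
    ("daytime_dysfunction", "duration"): 0.25,
    ("daytime_dysfunction", "efficiency"): 0.38,
    ("daytime_dysfunction", "disturbances"): 0.52,
    ("daytime_dysfunction", "sleep_quality"): 0.39,
    ("daytime_dysfunction", "medication"): 0.51,
}

#: the opposite-sign pair: signed contributions (contribA, contribE, rPH)
A_SHARE_SIGNED = {("medication", "duration"): (-0.08, 0.02, -0.06)}

#: latent-factor heritability of the one-factor common pathway model
LATENT_H2 = 0.32


def decompose_pair(i: str, j: str):
    """Run the bivariate decomposition on the published estimates of one
    trait pair."""
    from .biometric import decompose_phenotypic_correlation

    key = (i, j) if (i, j) in CORRELATIONS else (j, i)
    ra, re, _ = CORRELATIONS[key]
    return decompose_phenotypic_correlation(
        H2[key[0]], H2[key[1]], 1.0 - H2[key[0]], 1.0 - H2[key[1]], ra, re)


def a_share_from_published(i: str, j: str) -> float:
    """The published A-share computation for one pair: the genetic
    contribution rA sqrt(h2_i h2_j) divided by the *published* phenotypic
    correlation (the published tables round rPH independently, so the
    printed rPH — not the implied sum of contributions — is the
    denominator of the printed share)."""
    key = (i, j) if (i, j) in CORRELATIONS else (j, i)
    rph = CORRELATIONS[key][2]
    return float(decompose_pair(i, j).contribA / rph)
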