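"""Published national aggregates used for reconstruction cross-checks.

These are the printed stratified episode counts, treated percentages and
antibiotic-type counts from the national Norwegian primary-care registry
analysis of RTI antibiotic treatment, 2018-2021 (pre-pandemic window
2018-03-12 to 2019-11-30 vs pandemic window 2020-03-12 to 2021-11-30).
Individual-level registry data are not public; these aggregates let the
closed-form statistics be checked against independently computed published
values: treated counts are reconstructed from each (N, % treated) pair and
fed through :func:`rtiepi.stats.risk_ratio`.
"""

from __future__ import annotations

from .stats import TwoByTwo, two_by_two_from_printed

__all__ = ["STRATIFIED_TREATMENT", "PUBLISHED_RR", "TYPE_COUNTS_MARCH_WINDOW",
           "reconstruct_two_by_two"]

# stratum -> (n_pre, pct_treated_pre, n_pandemic, pct_treated_pandemic)
STRATIFIED_TREATMENT: dict[str, tuple[int, float, int, float]] = {
    "0-4": (310_384, 21.1, 200_348, 14.9),
    "5-14": (192_965, 24.0, 179_097, 9.7),
    "15-24": (357_801, 24.8, 292_241, 16.1),
    "25-34": (263_420, 26.1, 314_271, 11.2),
    "35-44": (226_333, 27.3, 272_171, 11.4),
    "45-54": (213_818, 26.5, 227_809, 11.9),
    "55-64": (189_547, 29.0, 172_006, 14.8),
    "65-74": (151_990, 32.0, 107_164, 18.9),
    "75-84": (84_289, 31.7, 59_055, 20.0),
    "85+": (33_520, 32.6, 21_483, 20.9),
    "Total": (2_024_067, 26.1, 1_845_645, 13.5),
    "DGP (1)": (1_418_207, 19.4, 1_102_172, 9.3),
    "OOH (1)": (210_610, 29.3, 233_232, 14.6),
    "DGP (2+)": (287_219, 46.1, 358_922, 18.4),
    "OOH (2+)": (14_016, 47.0, 19_239, 28.1),
    "Mixed (2+) service": (94_015, 56.5, 132_080, 31.1),
    "In-person (1)": (1_619_923, 20.7, 764_720, 13.3),
    "Electronic (1)": (8_894, 5.9, 570_684, 6.2),
    "In-person (2+)": (382_737, 48.9, 121_389, 34.5),
    "Electronic (2+)": (663, 10.9, 167_068, 8.2),
    "Mixed (2+) mode": (11_850, 39.6, 221_784, 25.7),
}

# stratum -> (RR, CI low, CI high) as printed, 2 decimals
PUBLISHED_RR: dict[str, tuple[float, float, float]] = {
    "0-4": (0.71, 0.70, 0.72),
    "5-14": (0.40, 0.40, 0.41),
    "15-24": (0.65, 0.64, 0.65),
    "25-34": (0.43, 0.43, 0.44),
    "35-44": (0.42, 0.41, 0.42),
    "45-54": (0.45, 0.44, 0.45),
    "55-64": (0.51, 0.50, 0.52),
    "65-74": (0.59, 0.58, 0.60),
    "75-84": (0.63, 0.62, 0.64),
    "85+": (0.64, 0.62, 0.66),
    "Total": (0.52, 0.52, 0.52),
    "DGP (1)": (0.48, 0.48, 0.48),
    "OOH (1)": (0.50, 0.49, 0.50),
    "DGP (2+)": (0.40, 0.40, 0.40),
    "OOH (2+)": (0.60, 0.58, 0.62),
    "Mixed (2+) service": (0.55, 0.55, 0.56),
    "In-person (1)": (0.64, 0.63, 0.64),
    "Electronic (1)": (1.06, 0.97, 1.15),
    "In-person (2+)": (0.71, 0.70, 0.71),
    "Electronic (2+)": (0.76, 0.61, 0.94),
    "Mixed (2+) mode": (0.65, 0.63, 0.66),
}

# antibiotic type -> counts in the 12 March - 12 April window of each year
# (published lockdown-anniversary comparison); column percentages were
# printed to 1 decimal
TYPE_COUNTS_MARCH_WINDOW: dict[str, dict[int, int]] = {
    "azithromycin": {2018: 1_327, 2019: 1_276, 2020: 663, 2021: 318},
    "other_macrolides": {2018: 4_250, 2019: 4_091, 2020: 2_617, 2021: 979},
    "phenoxymethylpenicillin": {2018: 19_430, 2019: 18_892, 2020: 10_569, 2021: 5_551},
    "other_penicillins": {2018: 4_921, 2019: 4_600, 2020: 2_778, 2021: 1_280},
    "tetracyclines": {2018: 4_583, 2019: 4_278, 2020: 2_719, 2021: 1_023},
    "other": {2018: 1_595, 2019: 1_573, 2020: 1_299, 2021: 612},
}


def reconstruct_two_by_two(stratum: str) -> TwoByTwo:
    """Reconstruct the treated/total counts of one published stratum."""
    return two_by_two_from_printed(*STRATIFIED_TREATMENT[stratum])
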