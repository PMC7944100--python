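"""Cohort-level correlation mapping of resting features against behavior.

For each (band, channel) cell — or each (band, channel-pair) coherence
edge — the cohort's feature values are correlated with a behavioral
measure by Pearson's r; two-tailed p-values come from the t transform
``t = |r| sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of
freedom.  Significance is uncorrected ``p < alpha`` by default (the
convention of electrode-wise exploratory mapping); a Benjamini-Hochberg
switch is provided as an extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import kruskal_wallis
from .errors import PairingError, ParameterError, UndefinedCorrelationError
from .montage import OCCIPITAL

MEASURES = ("mean_rt_ms", "accuracy_pct")


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    return float(stats.pearsonr(x, y).statistic)


def pearson_p(rho: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n, via the t transform."""
    if n < 3:
        raise UndefinedCorrelationError("need n >= 3")
    if not -1 <= rho <= 1:
        raise ParameterError("rho must be in [-1, 1]")
    if abs(rho) == 1.0:
        return 0.0  # limiting value; flagged by the caller if needed
    t = abs(rho) * np.sqrt(n - 2) / np.sqrt(1.0 - rho**2)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _match_subjects(
    feature_wide: pd.DataFrame, behavior: pd.DataFrame, measure: str
) -> pd.DataFrame:
    if measure not in behavior.columns:
        raise ParameterError(f"behavior table has no column {measure!r}")
    merged = feature_wide.merge(
        behavior[["subject", measure]], on="subject", how="inner"
    ).dropna(subset=[measure])
    if len(merged) < 3:
        raise UndefinedCorrelationError(
            f"only {len(merged)} subjects common to features and behavior"
        )
    return merged


def correlation_map(
    band_power: pd.DataFrame,
    behavior: pd.DataFrame,
    measure: str = "mean_rt_ms",
    power: str = "relative",
    condition: str = "eyes_closed",
    alpha: float = 0.05,
    multiplicity: str = "none",
) -> pd.DataFrame:
    """Electrode-wise Pearson correlation map of band power vs behavior.

    Parameters
    ----------
    band_power
        Long-format cohort table (subject, condition, channel, band,
        absolute_density, integrated_power[, relative_power]).
    behavior
        One row per subject with the behavioral measures.
    measure
        ``mean_rt_ms`` or ``accuracy_pct``.
    power
        Feature scale: ``relative`` (band's share of total power, the
        default for published maps) or ``absolute`` (mean density).
    condition
        Resting condition to map (eyes-closed is the biomarker
        condition).
    multiplicity
        ``none`` (uncorrected, default) or ``bh``.

    Returns one row per (band, channel): rho, p, n, significant.
    """
    col = {"relative": "relative_power", "absolute": "absolute_density"}.get(power)
    if col is None:
        raise ParameterError(f"power must be 'relative' or 'absolute', got {power!r}")
    if col not in band_power.columns:
        raise ParameterError(f"band-power table lacks column {col!r}")
    sub = band_power[band_power["condition"] == condition]
    if sub.empty:
        raise PairingError(f"no rows for condition {condition!r}")
    rows = []
    for (band, channel), grp in sub.groupby(["band", "channel"], sort=False):
        merged = _match_subjects(grp[["subject", col]], behavior, measure)
        r = pearson_r(merged[col], merged[measure])
        n = len(merged)
        rows.append({"band": band, "channel": channel, "rho": r,
                     "p": pearson_p(r, n), "n": n})
    out = pd.DataFrame(rows)
    out["significant"] = _flag(out["p"].to_numpy(), alpha, multiplicity)
    return out


def edge_correlation_network(
    edges: pd.DataFrame,
    behavior: pd.DataFrame,
    measure: str = "mean_rt_ms",
    condition: str = "eyes_closed",
    alpha: float = 0.05,
    multiplicity: str = "none",
) -> pd.DataFrame:
    """Pearson correlation of every coherence edge against behavior.

    ``edges`` is the long-format edge list produced by
    :meth:`resteeg.spectral.CoherenceNetwork.edge_list` concatenated
    over subjects.  Returns one row per (band, ch_i, ch_j).
    """
    sub = edges[edges["condition"] == condition]
    if sub.empty:
        raise PairingError(f"no edges for condition {condition!r}")
    rows = []
    for (band, ci, cj), grp in sub.groupby(["band", "ch_i", "ch_j"], sort=False):
        merged = _match_subjects(grp[["subject", "coherence"]], behavior, measure)
        r = pearson_r(merged["coherence"], merged[measure])
        n = len(merged)
        rows.append({"band": band, "ch_i": ci, "ch_j": cj, "rho": r,
                     "p": pearson_p(r, n), "n": n})
    out = pd.DataFrame(rows)
    out["significant"] = _flag(out["p"].to_numpy(), alpha, multiplicity)
    return out


def _flag(p: np.ndarray, alpha: float, multiplicity: str) -> np.ndarray:
    if multiplicity == "none":
        return p < alpha
    if multiplicity == "bh":
        return _bh_adjust(p) < alpha
    raise ParameterError(f"multiplicity must be 'none' or 'bh', got {multiplicity!r}")


def significant_edges_by_band(network: pd.DataFrame) -> dict[str, list]:
    """Per-band lists of significant edges, for external topographic plotting.

    Input is an :func:`edge_correlation_network` table; output maps each
    band to ``[{"edge": [ch_i, ch_j], "rho": r, "p": p}, ...]``.
    """
    out: dict[str, list] = {band: [] for band in network["band"].unique()}
    for row in network[network["significant"]].itertuples():
        out[row.band].append(
            {"edge": [row.ch_i, row.ch_j], "rho": float(row.rho), "p": float(row.p)}
        )
    return out


def ec_eo_alpha_contrast(
    band_power: pd.DataFrame, band: str = "alpha", channels=OCCIPITAL
) -> dict:
    """Eyes-closed vs eyes-open occipital alpha density contrast.

    Per subject and condition, alpha absolute density is averaged over
    the occipital sites; the group contrast is tested with
    Kruskal-Wallis.  Returns group means/SDs per condition and the test.
    """
    sub = band_power[
        (band_power["band"] == band) & (band_power["channel"].isin(channels))
    ]
    per_subject = (
        sub.groupby(["subject", "condition"])["absolute_density"].mean().unstack()
    )
    for cond in ("eyes_closed", "eyes_open"):
        if cond not in per_subject.columns or per_subject[cond].isna().any():
            raise PairingError(f"condition {cond!r} missing for some subjects")
    ec = per_subject["eyes_closed"].to_numpy()
    eo = per_subject["eyes_open"].to_numpy()
    h, p = kruskal_wallis(ec, eo)
    return {
        "ec_mean": float(ec.mean()),
        "ec_sd": float(ec.std(ddof=1)),
        "eo_mean": float(eo.mean()),
        "eo_sd": float(eo.std(ddof=1)),
        "kw_h": h,
        "kw_p": p,
        "n": int(per_subject.shape[0]),
    }
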