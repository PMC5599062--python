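"""Statistically significant looping-interaction ("5C peak") calling.

Per library: a Loess expected model (smoothing span 0.01) gives a weighted
mean and SD of contact frequency at each genomic distance; observed values
become Z scores; the Z-score distribution is fitted with a two-parameter
Weibull whose upper tail supplies p-values; Benjamini-Hochberg q-values are
thresholded at 0.05.  Only calls reproducible in both replicate libraries
are kept, and cell-type call sets are compared on the pairs interrogated in
all libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ContactMatrix, ProbeMap
from .normalization import DecayCurve, DegenerateFitError, global_distance_decay, z_score_grid

Q_THRESHOLD = 0.05


def expected_model(matrix: ContactMatrix, alpha: float = 0.01) -> DecayCurve:
    """Loess expected mean/SD per genomic distance on the normalized matrix."""
    return global_distance_decay(matrix, span=alpha)


def z_transform(
    matrix: ContactMatrix, model: DecayCurve, count_noise_floor: bool = False
) -> np.ma.MaskedArray:
    """(observed - expected) / sd on unmasked cells.

    With ``count_noise_floor`` the denominator of each cell is floored at the
    cell's own propagated counting noise, sqrt(scale_i * scale_j * expected):
    a Poisson count rescaled by the probe correction factors carries at least
    that much sampling SD, which the distance-pooled Loess SD underestimates
    for strongly corrected probes in sparse long-distance cells.
    """
    if not count_noise_floor:
        return z_score_grid(matrix, model)
    d = matrix.distance_grid()
    exp_ = model.expected_mean(d)
    sd_ = model.expected_sd(d)
    scale = matrix.fwd_scale[:, None] * matrix.rev_scale[None, :]
    floor = np.sqrt(np.clip(scale * exp_, 0.0, None))
    z = (matrix.values - exp_) / np.maximum(sd_, floor)
    return np.ma.MaskedArray(z, mask=matrix.mask)


@dataclass
class WeibullFit:
    """Two-parameter Weibull fitted to a (shifted) Z-score sample.

    ``support_shift`` is added to a Z score before evaluating the CDF; with
    ``mode="shift"`` it moves the whole sample to positive support, with
    ``mode="positive"`` only positive Z scores are fitted and non-positive
    scores get p = 1.
    """

    shape: float
    scale: float
    support_shift: float
    n_fitted: int
    mode: str = "shift"

    def p_value(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        shifted = np.clip(z + self.support_shift, 0.0, None)
        return stats.weibull_min.sf(shifted, self.shape, loc=0.0, scale=self.scale)


def fit_weibull(z_values: np.ndarray, mode: str = "shift", eps: float = 1e-6) -> WeibullFit:
    """Maximum-likelihood Weibull fit of a Z-score sample.

    ``mode="shift"`` (default) shifts all values to positive support by
    ``-min(z) + eps`` and records the shift; ``mode="positive"`` fits the
    positive values only.
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 100:
        raise ValueError("need >= 100 finite Z values to fit a Weibull")
    if np.allclose(z, z[0]):
        raise DegenerateFitError("all Z values identical; Weibull fit degenerate")
    if mode == "shift":
        shift = -float(z.min()) + eps
        sample = z + shift
    elif mode == "positive":
        shift = 0.0
        sample = z[z > 0]
        if sample.size < 100:
            raise ValueError("fewer than 100 positive Z values")
    else:
        raise ValueError(f"unknown weibull mode {mode!r}")
    shape, _loc, scale = stats.weibull_min.fit(sample, floc=0.0)
    return WeibullFit(shape=float(shape), scale=float(scale), support_shift=shift,
                      n_fitted=int(sample.size), mode=mode)


def call_peaks(
    matrix: ContactMatrix,
    model: DecayCurve,
    fit: WeibullFit,
    q_threshold: float = Q_THRESHOLD,
    fdr_method: str = "fdr_bh",
    count_noise_floor: bool = True,
) -> pd.DataFrame:
    """Per-library loop calls: one row per unmasked interrogated pair.

    p-values come from the Weibull upper tail of the Z score; q-values from
    Benjamini-Hochberg over all unmasked cells of the library.  A call is
    significant iff q < ``q_threshold``.  The cell-level counting-noise
    floor (see :func:`z_transform`) is on by default.
    """
    pm = matrix.probe_map
    z = z_transform(matrix, model, count_noise_floor=count_noise_floor)
    sel = ~matrix.mask
    fi, rj = np.nonzero(sel)
    zv = np.asarray(z[fi, rj])
    p = fit.p_value(zv)
    _rej, q, _a, _b = multipletests(p, method=fdr_method)
    d = matrix.distance_grid()
    exp_ = model.expected_mean(d[fi, rj])
    sd_ = model.expected_sd(d[fi, rj])
    df = pd.DataFrame(
        {
            "fwd_id": [pm.forward[i].probe_id for i in fi],
            "rev_id": [pm.reverse[j].probe_id for j in rj],
            "chrom": pm.span.chrom,
            "fwd_mid": pm.fwd_mids[fi].astype(int),
            "rev_mid": pm.rev_mids[rj].astype(int),
            "distance_bp": d[fi, rj].astype(int),
            "obs": matrix.values[fi, rj],
            "exp": exp_,
            "sd": sd_,
            "z": zv,
            "p": p,
            "q": q,
        }
    )
    df["significant"] = df["q"] < q_threshold
    df["replicate_support"] = matrix.library_label
    return df


def call_library(
    matrix: ContactMatrix,
    alpha: float = 0.01,
    q_threshold: float = Q_THRESHOLD,
    weibull_mode: str = "shift",
    count_noise_floor: bool = True,
) -> pd.DataFrame:
    """Expected model -> Z -> Weibull -> BH for a single normalized library."""
    model = expected_model(matrix, alpha)
    z = z_transform(matrix, model, count_noise_floor=count_noise_floor)
    fit = fit_weibull(np.asarray(z[~z.mask]), mode=weibull_mode)
    return call_peaks(matrix, model, fit, q_threshold,
                      count_noise_floor=count_noise_floor)


def replicate_consensus(
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    probe_map_1: ProbeMap | None = None,
    probe_map_2: ProbeMap | None = None,
) -> pd.DataFrame:
    """Pairs significant in both replicates and interrogated in both.

    The consensus q of a pair is the max of the two replicate q-values
    (conservative); observed/expected/Z are averaged for reporting.
    """
    if probe_map_1 is not None and probe_map_2 is not None and probe_map_1 != probe_map_2:
        raise ValueError("replicate probe maps differ")
    key = ["fwd_id", "rev_id"]
    sig1 = calls_rep1[calls_rep1["significant"]]
    sig2 = calls_rep2[calls_rep2["significant"]]
    merged = sig1.merge(sig2, on=key, suffixes=("_1", "_2"))
    if merged.empty:
        cols = list(calls_rep1.columns)
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(
        {
            "fwd_id": merged["fwd_id"],
            "rev_id": merged["rev_id"],
            "chrom": merged["chrom_1"],
            "fwd_mid": merged["fwd_mid_1"],
            "rev_mid": merged["rev_mid_1"],
            "distance_bp": merged["distance_bp_1"],
            "obs": (merged["obs_1"] + merged["obs_2"]) / 2,
            "exp": (merged["exp_1"] + merged["exp_2"]) / 2,
            "sd": (merged["sd_1"] + merged["sd_2"]) / 2,
            "z": (merged["z_1"] + merged["z_2"]) / 2,
            "p": np.maximum(merged["p_1"], merged["p_2"]),
            "q": np.maximum(merged["q_1"], merged["q_2"]),
        }
    )
    out["significant"] = True
    out["replicate_support"] = (
        merged["replicate_support_1"] + "," + merged["replicate_support_2"]
    )
    out = out.drop_duplicates(subset=key).reset_index(drop=True)
    return out


def interrogated_in_all(call_tables: list[pd.DataFrame]) -> set[tuple[str, str]]:
    """Pairs present (unmasked after QC) in every per-library call table."""
    sets = [set(zip(t["fwd_id"], t["rev_id"])) for t in call_tables]
    common = sets[0]
    for s in sets[1:]:
        common = common & s
    return common


def compare_cell_types(
    consensus_a: pd.DataFrame,
    consensus_b: pd.DataFrame,
    interrogated: set[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-type-specific and common consensus calls, restricted to the
    pairs interrogated in all contributing libraries.

    Returns (A-specific, B-specific, common); the three sets are disjoint.
    """
    def keyset(df):
        return set(zip(df["fwd_id"], df["rev_id"])) & interrogated

    ka, kb = keyset(consensus_a), keyset(consensus_b)
    common_keys = ka & kb

    def subset(df, keys):
        sel = [k in keys for k in zip(df["fwd_id"], df["rev_id"])]
        return df[sel].reset_index(drop=True)

    return (
        subset(consensus_a, ka - common_keys),
        subset(consensus_b, kb - common_keys),
        subset(consensus_a, common_keys),
    )
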