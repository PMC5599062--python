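"""5C technical-bias correction.

The correction scheme follows the classic single-locus 5C workflow:

1. *cis-purge* — drop probes whose own contact-vs-distance profile deviates
   from the global distance decay (systematically misbehaving probes);
2. *singleton removal* — mask isolated extreme cells (Z >= 25 against the
   distance-matched expectation);
3. *profile normalization* — rescale every probe's profile so it matches the
   global decay curve, removing multiplicative per-probe efficiency biases;
4. *binning* — overlapping windows (150 kb, 15 kb step) whose statistic is the
   mean over contributing interrogated pairs, neutralizing uneven probe
   coverage.

The expected contact level at a genomic distance is estimated by Loess-style
locally weighted regression, which yields a weighted mean *and* a weighted
standard deviation per distance; both are needed for the Z score
(observed - expected) / sd used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ContactMatrix

# SD floor parameters: sd is never allowed below max(rel * mean, abs floor),
# so Z stays finite on near-constant strata.
SD_FLOOR_REL = 1e-3
SD_FLOOR_ABS = 1e-9


class DegenerateFitError(ValueError):
    """Raised when a smoothing fit has no usable distance support."""


@dataclass
class DecayCurve:
    """Smoothed mean/SD of contact signal as a function of genomic distance.

    Queries between support points use monotone (linear) interpolation;
    queries outside the support are clamped to the nearest end.
    """

    support: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    smoothing_span: float

    def expected_mean(self, d) -> np.ndarray:
        return np.interp(d, self.support, self.mean)

    def expected_sd(self, d) -> np.ndarray:
        return np.interp(d, self.support, self.sd)


def _tricube(u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    a *= a * a  # |u|^3 without pow
    w = 1.0 - a
    np.clip(w, 0.0, None, out=w)
    w *= w * w
    return w


def loess_fit(
    distances: np.ndarray,
    values: np.ndarray,
    span: float,
    *,
    max_support: int = 1500,
    min_window: int = 5,
) -> DecayCurve:
    """Locally weighted mean and SD of ``values`` against ``distances``.

    For each support distance the window is the minimal contiguous run of the
    ``k`` nearest points (k = ceil(span * n), at least ``min_window``),
    weighted by the tricube kernel.  The weighted SD gets the module-level
    floor applied.
    """
    d = np.asarray(distances, dtype=float).ravel()
    v = np.asarray(values, dtype=float).ravel()
    if d.size != v.size:
        raise ValueError("distances and values differ in length")
    if d.size == 0:
        raise DegenerateFitError("no points to fit")
    order = np.argsort(d, kind="mergesort")
    d, v = d[order], v[order]
    uniq = np.unique(d)
    if uniq.size < 2:
        raise DegenerateFitError("all cells at a single genomic distance")

    n = d.size
    k = min(n, max(min_window, int(np.ceil(span * n))))

    if uniq.size > max_support:
        idx = np.unique(np.linspace(0, uniq.size - 1, max_support).round().astype(int))
        support = uniq[idx]
    else:
        support = uniq

    if n * support.size <= 2_000_000:
        means, sds = _loess_eval_dense(d, v, support, k)
    else:
        means, sds = _loess_eval_windowed(d, v, support, k)
    sds = np.maximum(sds, np.maximum(SD_FLOOR_REL * np.abs(means), SD_FLOOR_ABS))
    return DecayCurve(support=support, mean=means, sd=sds, smoothing_span=span)


def _loess_eval_dense(d, v, support, k):
    """Vectorized tricube-weighted mean/SD; O(len(support) * len(d)) memory."""
    A = np.abs(d[None, :] - support[:, None])
    h = np.partition(A, k - 1, axis=1)[:, k - 1]
    zero_h = h <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = _tricube(A / (np.where(zero_h, 1.0, h)[:, None] * 1.0001))
    if np.any(zero_h):
        W[zero_h] = (A[zero_h] == 0).astype(float)
    wsum = W.sum(axis=1)
    m = (W @ v) / wsum
    var = (W @ (v * v)) / wsum - m * m
    return m, np.sqrt(np.clip(var, 0.0, None))


def _loess_eval_windowed(d, v, support, k):
    """Sliding-window evaluation for large samples (d sorted ascending)."""
    n = d.size
    means = np.empty(support.size)
    sds = np.empty(support.size)
    for s, x in enumerate(support):
        pos = np.searchsorted(d, x)
        lo_min = max(0, pos - k)
        lo_max = min(pos, n - k)
        if lo_max < lo_min:
            lo = lo_min
        else:
            los = np.arange(lo_min, lo_max + 1)
            # minimal window: smallest max-distance to x among contiguous runs
            spans_ = np.maximum(np.abs(d[los + k - 1] - x), np.abs(d[los] - x))
            lo = los[np.argmin(spans_)]
        window_d = d[lo : lo + k]
        window_v = v[lo : lo + k]
        h = np.max(np.abs(window_d - x))
        if h == 0:
            w = np.ones_like(window_v)
        else:
            w = _tricube((window_d - x) / (h * 1.0001))
            if not np.any(w > 0):
                w = np.ones_like(window_v)
        wsum = w.sum()
        m = float(np.dot(w, window_v) / wsum)
        var = float(np.dot(w, (window_v - m) ** 2) / wsum)
        means[s] = m
        sds[s] = np.sqrt(var)
    return means, sds


def global_distance_decay(matrix: ContactMatrix, span: float = 0.05) -> DecayCurve:
    """Global contact-frequency vs genomic-distance curve for one library.

    Fitted on unmasked cells only; distances are between the forward and
    reverse fragment midpoints.
    """
    mask = matrix.mask
    if (~mask).sum() < 50:
        raise DegenerateFitError("fewer than 50 unmasked cells")
    d = matrix.distance_grid()[~mask]
    v = matrix.values[~mask]
    return loess_fit(d, v, span)


def z_score_grid(matrix: ContactMatrix, decay: DecayCurve) -> np.ma.MaskedArray:
    """(observed - expected) / expected_sd per cell; masked cells propagate."""
    d = matrix.distance_grid()
    z = (matrix.values - decay.expected_mean(d)) / decay.expected_sd(d)
    return np.ma.MaskedArray(z, mask=matrix.mask)


# ---------------------------------------------------------------------------
# probe cis-purge

@dataclass
class ProbeQC:
    """Per-probe deviation scores from the cis-purge stage."""

    scores: dict[str, float]
    removed: list[str]
    insufficient: list[str]
    threshold: float
    scaling: str


def _iter_probe_profiles(matrix: ContactMatrix):
    """Yield (probe_id, orientation-axis index, distances, values, unmasked sel)."""
    pm = matrix.probe_map
    mask = matrix.mask
    dgrid = matrix.distance_grid()
    for i, probe in enumerate(pm.forward):
        sel = ~mask[i, :]
        yield probe.probe_id, ("fwd", i), dgrid[i, sel], matrix.values[i, sel], sel
    for j, probe in enumerate(pm.reverse):
        sel = ~mask[:, j]
        yield probe.probe_id, ("rev", j), dgrid[sel, j], matrix.values[sel, j], sel


def purge_cis_probes(
    matrix: ContactMatrix,
    decay: DecayCurve,
    deviation_threshold: float = 0.85,
    *,
    scaling: str = "sd_units",
    min_cells: int = 5,
    trim_z: float = 25.0,
) -> tuple[ContactMatrix, ProbeQC]:
    """Remove probes whose smoothed profile strays from the global decay.

    Each probe's own cells are Loess-smoothed (same span as the global fit);
    the probe's score is the mean absolute deviation of that smoothed profile
    from the global curve, in units of the global expected SD — the scaled
    Z-score distance of the probe from the global Loess.  With
    ``scaling="sd_units"`` (default) that score is thresholded directly at
    ``deviation_threshold``; ``scaling="zscore"`` first standardizes the
    scores across probes.  Probes with fewer than ``min_cells`` unmasked cells
    are flagged insufficient and never purged.

    Scoring is made robust to singleton spikes: cells beyond ``trim_z`` are
    excluded from the profiles and from the reference curve while scoring
    (they would otherwise inflate the SD denominator and hide bad probes),
    but their removal is left to the singleton stage — the returned matrix
    only gains probe masks.
    """
    if scaling not in ("sd_units", "zscore"):
        raise ValueError(f"unknown scaling {scaling!r}")

    work = matrix.copy()
    ref = decay
    if trim_z is not None:
        for _ in range(2):  # spikes can shield each other in the first pass
            extreme = np.asarray(
                (z_score_grid(work, ref) >= trim_z).filled(False)
            )
            if not extreme.any():
                break
            work.cell_mask |= extreme
            ref = loess_fit(
                work.distance_grid()[~work.mask],
                work.values[~work.mask],
                decay.smoothing_span,
            )

    scores: dict[str, float] = {}
    insufficient: list[str] = []
    for probe_id, _, d, v, _sel in _iter_probe_profiles(work):
        if d.size < min_cells:
            insufficient.append(probe_id)
            continue
        try:
            curve = loess_fit(d, v, decay.smoothing_span, max_support=128)
            # reference = global curve smoothed with the same window on the
            # same cells, so the smoothing (curvature) bias cancels
            ref_curve = loess_fit(
                d, ref.expected_mean(d), decay.smoothing_span, max_support=128
            )
        except DegenerateFitError:
            insufficient.append(probe_id)
            continue
        dev = (curve.mean - ref_curve.expected_mean(curve.support)) / ref.expected_sd(
            curve.support
        )
        scores[probe_id] = float(np.mean(np.abs(dev)))

    if scaling == "zscore" and scores:
        vals = np.array(list(scores.values()))
        sd = vals.std()
        if sd > 0:
            scores = {k: (s - vals.mean()) / sd for k, s in scores.items()}
        else:
            scores = {k: 0.0 for k in scores}

    removed = sorted(k for k, s in scores.items() if abs(s) > deviation_threshold)

    out = matrix.copy()
    pm = matrix.probe_map
    for pid in removed:
        probe = pm[pid]
        if probe.orientation == "forward":
            out.fwd_probe_mask[pm.fwd_index(pid)] = True
        else:
            out.rev_probe_mask[pm.rev_index(pid)] = True
    qc = ProbeQC(scores, removed, insufficient, deviation_threshold, scaling)
    return out, qc


# ---------------------------------------------------------------------------
# singleton removal

def remove_singletons(
    matrix: ContactMatrix, decay: DecayCurve, z_threshold: float = 25.0
) -> tuple[ContactMatrix, list[tuple[str, str]]]:
    """Mask isolated extreme cells with Z >= ``z_threshold`` (inclusive).

    These "singletons" are contact values wildly above the distance-matched
    neighbourhood, treated as ligation/PCR artifacts rather than biology.
    Returns the updated matrix and the (fwd_id, rev_id) pairs removed.
    """
    z = z_score_grid(matrix, decay)
    hits = np.asarray((z >= z_threshold).filled(False))
    out = matrix.copy()
    out.cell_mask |= hits
    pm = matrix.probe_map
    removed = [
        (pm.forward[i].probe_id, pm.reverse[j].probe_id)
        for i, j in zip(*np.nonzero(hits))
    ]
    return out, removed


# ---------------------------------------------------------------------------
# profile normalization

def normalize_profiles(
    matrix: ContactMatrix, decay: DecayCurve
) -> tuple[ContactMatrix, dict[str, float]]:
    """Rescale each probe's profile onto the global decay curve.

    The correction factor of a probe is the median over its unmasked cells of
    the ratio of the global curve to the probe's own smoothed profile (median
    rather than mean: single extreme cells — residual spikes, planted loops —
    and near-zero smoothed values in sparse long-distance cells must not
    drag the factor); each cell is multiplied by the factors of both probes.
    Probes whose profile is all zero cannot be corrected and are masked.
    Returns the normalized matrix and the per-probe factors.
    """
    pm = matrix.probe_map
    factors: dict[str, float] = {}
    fwd_f = np.ones(len(pm.forward))
    rev_f = np.ones(len(pm.reverse))
    out = matrix.copy()
    for probe_id, (axis, idx), d, v, _sel in _iter_probe_profiles(matrix):
        if d.size == 0 or not np.any(v > 0):
            if d.size > 0:  # all-zero profile: cannot be rescaled
                if axis == "fwd":
                    out.fwd_probe_mask[idx] = True
                else:
                    out.rev_probe_mask[idx] = True
            continue
        try:
            curve = loess_fit(d, v, decay.smoothing_span, max_support=128)
        except DegenerateFitError:
            continue
        probe_smooth = curve.expected_mean(d)
        ok = probe_smooth > 0
        if not np.any(ok):
            if axis == "fwd":
                out.fwd_probe_mask[idx] = True
            else:
                out.rev_probe_mask[idx] = True
            continue
        f = float(np.median(decay.expected_mean(d[ok]) / probe_smooth[ok]))
        factors[probe_id] = f
        if axis == "fwd":
            fwd_f[idx] = f
        else:
            rev_f[idx] = f
    out.values = matrix.values * fwd_f[:, None] * rev_f[None, :]
    out.fwd_scale = matrix.fwd_scale * fwd_f
    out.rev_scale = matrix.rev_scale * rev_f
    return out, factors


# ---------------------------------------------------------------------------
# binning

@dataclass
class BinnedMatrix:
    """Overlapping-window aggregation of a contact matrix.

    ``values[a, b]`` is the mean normalized signal over unmasked interrogated
    pairs whose fragment midpoints fall into windows *a* and *b* (symmetrized
    over probe orientation); ``coverage`` counts the contributing pairs and
    zero-coverage bin pairs are masked.
    """

    bin_starts: np.ndarray
    bin_size: int
    step: int
    values: np.ndarray
    coverage: np.ndarray
    chrom: str = ""

    @property
    def bin_mids(self) -> np.ndarray:
        return self.bin_starts + self.bin_size / 2.0

    @property
    def mask(self) -> np.ndarray:
        return self.coverage == 0

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)


def bin_matrix(
    matrix: ContactMatrix,
    bin_size: int = 150_000,
    step: int = 15_000,
    region=None,
) -> BinnedMatrix:
    """Bin a (normalized) matrix into overlapping windows.

    Windows of width ``bin_size`` start every ``step`` bp from the region
    start; only fully contained windows are emitted.  The per-bin-pair
    statistic is the mean of contributing unmasked cells.
    """
    if bin_size < step:
        raise ValueError("bin_size must be >= step")
    span = region if region is not None else matrix.probe_map.span
    starts = np.arange(span.start, span.end - bin_size + 1, step)
    if starts.size == 0:
        raise ValueError("region shorter than one bin")
    nb = starts.size
    sums = np.zeros((nb, nb))
    counts = np.zeros((nb, nb), dtype=int)

    mask = matrix.mask
    sel = ~mask
    fi, rj = np.nonzero(sel)
    vals = matrix.values[fi, rj]
    fm = matrix.probe_map.fwd_mids[fi]
    rm = matrix.probe_map.rev_mids[rj]

    def window_hits(mids):
        """For each midpoint, the range of window indices containing it."""
        base = np.floor((mids - span.start) / step).astype(int)
        n_over = bin_size // step
        cols = []
        for off in range(n_over):
            k = base - off
            ok = (k >= 0) & (k < nb) & (mids >= starts[np.clip(k, 0, nb - 1)]) & (
                mids < starts[np.clip(k, 0, nb - 1)] + bin_size
            )
            cols.append((k, ok))
        return cols

    for ka, oka in window_hits(fm):
        for kb, okb in window_hits(rm):
            ok = oka & okb
            if not np.any(ok):
                continue
            np.add.at(sums, (ka[ok], kb[ok]), vals[ok])
            np.add.at(counts, (ka[ok], kb[ok]), 1)

    tot = sums + sums.T
    cov = counts + counts.T
    # diagonal was not double-counted by the transpose trick only off-diagonal;
    # recompute diagonal directly
    np.fill_diagonal(tot, 2 * np.diag(sums))
    np.fill_diagonal(cov, 2 * np.diag(counts))
    values = np.zeros_like(tot)
    nz = cov > 0
    values[nz] = tot[nz] / cov[nz]
    return BinnedMatrix(
        bin_starts=starts,
        bin_size=bin_size,
        step=step,
        values=values,
        coverage=cov,
        chrom=span.chrom,
    )


# ---------------------------------------------------------------------------
# full QC pipeline

@dataclass
class NormalizationResult:
    matrix: ContactMatrix
    decay_raw: DecayCurve
    decay_final: DecayCurve
    probe_qc: ProbeQC
    singletons: list[tuple[str, str]] = field(default_factory=list)
    factors: dict[str, float] = field(default_factory=dict)


def normalize_library(
    matrix: ContactMatrix,
    *,
    span: float = 0.05,
    purge_threshold: float = 0.85,
    purge_scaling: str = "sd_units",
    singleton_z: float = 25.0,
    singleton_passes: int = 5,
) -> NormalizationResult:
    """Run purge -> singleton removal -> profile normalization on one library.

    The decay curve is re-estimated after the purge so the singleton Z and
    the correction factors do not see the removed probes.  Singleton removal
    is repeated (with a refreshed decay curve) until no new cell is masked or
    ``singleton_passes`` is reached: extreme spikes inflate the local SD and
    can shield each other from a single pass.
    """
    decay0 = global_distance_decay(matrix, span)
    purged, qc = purge_cis_probes(
        matrix, decay0, purge_threshold, scaling=purge_scaling
    )
    cleaned = purged
    singles: list[tuple[str, str]] = []
    for _ in range(max(1, singleton_passes)):
        decay1 = global_distance_decay(cleaned, span)
        cleaned, new_singles = remove_singletons(cleaned, decay1, singleton_z)
        singles.extend(new_singles)
        if not new_singles:
            break
    decay2 = global_distance_decay(cleaned, span)
    normalized, factors = normalize_profiles(cleaned, decay2)
    return NormalizationResult(
        matrix=normalized,
        decay_raw=decay0,
        decay_final=decay2,
        probe_qc=qc,
        singletons=singles,
        factors=factors,
    )
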