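"""Insulation-index TAD boundary detection and gene-density classification.

A bin's insulation is the summed contact signal crossing it within a fixed
window (default 500 kb each side), normalized by the mean over all scored
bins.  Local minima of the insulation profile mark TAD boundaries; boundaries
called independently per replicate are consolidated by averaging matched
midpoints.  TADs are classified gene-rich or gene-poor by kb-per-gene against
the genome-average gene density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval
from .normalization import BinnedMatrix


@dataclass
class InsulationProfile:
    """Per-bin insulation scores; unscored (edge) bins carry NaN."""

    bin_mid: np.ndarray
    raw_sum: np.ndarray
    score: np.ndarray
    window: int
    chrom: str = ""

    @property
    def scored(self) -> np.ndarray:
        return ~np.isnan(self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid": self.bin_mid, "raw_sum": self.raw_sum, "score": self.score}
        )


@dataclass
class Boundary:
    """A TAD boundary: consolidated midpoint plus per-replicate detail."""

    midpoint: float
    replicate_midpoints: list[float]
    score_at_min: float
    strength: float = float("nan")


@dataclass
class TadSet:
    """Ordered TAD intervals partitioning the analyzed region."""

    tads: list[GenomicInterval]
    classes: list[str] = field(default_factory=list)
    kb_per_gene: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.classes:
            self.classes = ["unclassified"] * len(self.tads)
        if not self.kb_per_gene:
            self.kb_per_gene = [float("nan")] * len(self.tads)

    def tad_index_of(self, position: float) -> int | None:
        """Index of the TAD containing ``position`` (half-open), else None."""
        for i, tad in enumerate(self.tads):
            if tad.start <= position < tad.end:
                return i
        return None


def insulation_profile(binned: BinnedMatrix, window: int = 500_000) -> InsulationProfile:
    """Insulation score per bin of a binned contact matrix.

    ``raw_sum(b)`` sums the binned signal over bin pairs (x, y) with
    ``mid(x)`` in ``[mid(b) - window, mid(b)]`` and ``mid(y)`` in
    ``[mid(b), mid(b) + window]`` — the square of contacts crossing bin *b*.
    Bins whose window does not fit inside the binned range are left unscored.
    The score is ``raw_sum`` divided by its mean over scored bins.
    """
    mids = binned.bin_mids
    if mids[-1] - mids[0] < 2 * window:
        raise ValueError("binned matrix must cover at least twice the window")
    vals = np.where(binned.mask, 0.0, binned.values)
    n = binned.n_bins
    raw = np.full(n, np.nan)
    # prefix sums over the bin-pair grid for O(1) rectangle sums
    csum = np.zeros((n + 1, n + 1))
    csum[1:, 1:] = np.cumsum(np.cumsum(vals, axis=0), axis=1)

    lo = np.searchsorted(mids, mids - window, side="left")
    hi = np.searchsorted(mids, mids + window, side="right") - 1
    for b in range(n):
        if mids[b] - window < mids[0] or mids[b] + window > mids[-1]:
            continue
        x0, x1 = lo[b], b  # upstream bins, inclusive
        y0, y1 = b, hi[b]  # downstream bins, inclusive
        raw[b] = (
            csum[x1 + 1, y1 + 1] - csum[x0, y1 + 1] - csum[x1 + 1, y0] + csum[x0, y0]
        )
    scored = ~np.isnan(raw)
    if not np.any(scored) or np.nansum(raw) == 0:
        raise ValueError("empty matrix: all insulation sums are zero")
    mean = np.nanmean(raw)
    score = raw / mean
    return InsulationProfile(
        bin_mid=mids, raw_sum=raw, score=score, window=window, chrom=binned.chrom
    )


def find_boundaries(
    profile: InsulationProfile, minima_window: int = 435_000
) -> list[Boundary]:
    """Local insulation minima: boundaries of one replicate.

    A scored bin is a boundary iff its score is the minimum among all scored
    bins whose midpoints lie within +/- ``minima_window / 2`` of it, with
    ties broken to the leftmost bin.  Edge bins are already unscored and so
    never called.
    """
    mids = profile.bin_mid
    score = profile.score
    scored_idx = np.nonzero(profile.scored)[0]
    half = minima_window / 2.0
    boundaries: list[Boundary] = []
    for b in scored_idx:
        nb = scored_idx[np.abs(mids[scored_idx] - mids[b]) <= half]
        others = nb[nb != b]
        if others.size == 0:
            continue
        if np.any(
            (score[others] < score[b])
            | ((score[others] == score[b]) & (others < b))
        ):
            continue
        if not np.any(score[others] > score[b]):
            continue  # flat window: no genuine minimum
        left = others[others < b]
        right = others[others > b]
        lmax = np.max(score[left]) if left.size else np.nan
        rmax = np.max(score[right]) if right.size else np.nan
        strength = float(np.nanmin([lmax, rmax]) - score[b]) if others.size else np.nan
        boundaries.append(
            Boundary(
                midpoint=float(mids[b]),
                replicate_midpoints=[float(mids[b])],
                score_at_min=float(score[b]),
                strength=strength,
            )
        )
    return boundaries


@dataclass
class ConsolidationResult:
    consolidated: list[Boundary]
    replicate_specific: list[tuple[int, Boundary]]  # (replicate index, boundary)


def consolidate_boundaries(
    per_replicate: list[list[Boundary]], match_radius: int = 200_000
) -> ConsolidationResult:
    """Match boundaries across replicates and average matched midpoints.

    Greedy nearest-pair matching within ``match_radius``: the consolidated
    midpoint is the arithmetic mean of the matched replicate midpoints.
    Boundaries left unmatched are reported as replicate-specific.
    """
    if len(per_replicate) < 2:
        raise ValueError("need boundaries from at least 2 replicates")

    clusters: list[list[tuple[int, Boundary]]] = [
        [(0, b)] for b in per_replicate[0]
    ]
    specific: list[tuple[int, Boundary]] = []
    for r in range(1, len(per_replicate)):
        cand = []
        for ci, members in enumerate(clusters):
            cmid = np.mean([b.midpoint for _, b in members])
            for bi, b in enumerate(per_replicate[r]):
                d = abs(b.midpoint - cmid)
                if d <= match_radius:
                    cand.append((d, ci, bi))
        cand.sort()
        used_c: set[int] = set()
        used_b: set[int] = set()
        for d, ci, bi in cand:
            if ci in used_c or bi in used_b:
                continue
            clusters[ci].append((r, per_replicate[r][bi]))
            used_c.add(ci)
            used_b.add(bi)
        for bi, b in enumerate(per_replicate[r]):
            if bi not in used_b:
                specific.append((r, b))

    consolidated: list[Boundary] = []
    for members in clusters:
        if len(members) < 2:
            specific.extend(members)
            continue
        mids = [b.midpoint for _, b in members]
        consolidated.append(
            Boundary(
                midpoint=float(np.mean(mids)),
                replicate_midpoints=mids,
                score_at_min=float(np.mean([b.score_at_min for _, b in members])),
                strength=float(np.mean([b.strength for _, b in members])),
            )
        )
    consolidated.sort(key=lambda b: b.midpoint)
    specific.sort(key=lambda rb: rb[1].midpoint)
    return ConsolidationResult(consolidated, specific)


def tads_from_boundaries(
    boundaries: list[Boundary], region: GenomicInterval
) -> TadSet:
    """Partition the region into TADs delimited by boundary midpoints."""
    cuts = sorted(int(round(b.midpoint)) for b in boundaries)
    for c in cuts:
        if not (region.start < c < region.end):
            raise ValueError(f"boundary midpoint {c} outside region")
    edges = [region.start, *cuts, region.end]
    tads = [
        GenomicInterval(region.chrom, a, b, f"TAD{i + 1}")
        for i, (a, b) in enumerate(zip(edges, edges[1:]))
    ]
    return TadSet(tads=tads)


def classify_tads_by_gene_density(
    tads: TadSet,
    genes: pd.DataFrame,
    genome_avg_kb_per_gene: float = 75.0,
) -> TadSet:
    """Label TADs gene-rich or gene-poor by kb-per-gene vs the genome average.

    ``kb_per_gene`` = TAD length / number of TSSs inside it; a TAD is
    gene-rich when that is below ``genome_avg_kb_per_gene`` (default 75 kb
    per gene, the mouse genome average), else gene-poor.  A TAD with zero
    genes is gene-poor with kb_per_gene undefined (NaN).
    """
    classes: list[str] = []
    kbg: list[float] = []
    tss = genes["tss"].to_numpy()
    chroms = genes["chrom"].to_numpy()
    for tad in tads.tads:
        n = int(np.sum((chroms == tad.chrom) & (tss >= tad.start) & (tss < tad.end)))
        if n == 0:
            classes.append("gene_poor")
            kbg.append(float("nan"))
            continue
        k = (len(tad) / 1000.0) / n
        kbg.append(k)
        classes.append("gene_rich" if k < genome_avg_kb_per_gene else "gene_poor")
    return TadSet(tads=list(tads.tads), classes=classes, kb_per_gene=kbg)


def call_tads(
    binned_replicates: list[BinnedMatrix],
    region: GenomicInterval,
    *,
    window: int = 500_000,
    minima_window: int = 435_000,
    match_radius: int = 200_000,
) -> tuple[TadSet, ConsolidationResult, list[InsulationProfile]]:
    """Insulation -> per-replicate boundaries -> consolidation -> TadSet."""
    profiles = [insulation_profile(bm, window) for bm in binned_replicates]
    per_rep = [find_boundaries(p, minima_window) for p in profiles]
    if len(per_rep) >= 2:
        result = consolidate_boundaries(per_rep, match_radius)
    else:
        result = ConsolidationResult(per_rep[0], [])
    tset = tads_from_boundaries(result.consolidated, region)
    if not result.consolidated:
        warnings.warn("no consolidated boundaries; single TAD spanning region")
    return tset, result, profiles
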