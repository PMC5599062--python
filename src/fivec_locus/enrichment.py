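"""Protein-binding enrichment at loop anchors.

Anchors are restriction fragments extended to include the nearest adjacent
fragments interrogated by probes of the opposite orientation (the opposite-
strand neighbours), since a 5C probe only tags one end of a ligation
junction.  Binding is any >= 1 bp peak overlap with either extended anchor;
enrichment of binding among significant loops versus background interactions
is tested with the two-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FORWARD, GenomicInterval, ProbeMap


@dataclass(frozen=True)
class ExtendedAnchor:
    fragment: GenomicInterval
    extended: GenomicInterval


def extend_anchor(probe_id: str, probe_map: ProbeMap) -> ExtendedAnchor:
    """Extend a probe's fragment to its nearest opposite-orientation
    neighbours on each side; at a region edge the extension is one-sided.
    """
    if probe_id not in probe_map:
        raise KeyError(f"probe {probe_id!r} not in probe map")
    probe = probe_map[probe_id]
    probes = probe_map.probes
    idx = probes.index(probe)
    other = "reverse" if probe.orientation == FORWARD else FORWARD
    left = next(
        (p for p in reversed(probes[:idx]) if p.orientation == other), None
    )
    right = next((p for p in probes[idx + 1 :] if p.orientation == other), None)
    if left is None and right is None:
        warnings.warn(
            f"probe map has a single orientation; anchor {probe_id} not extended"
        )
    start = left.frag_start if left is not None else probe.frag_start
    end = right.frag_end if right is not None else probe.frag_end
    return ExtendedAnchor(
        fragment=probe.fragment,
        extended=GenomicInterval(probe.chrom, start, end, f"{probe_id}_ext"),
    )


def anchor_binding(
    loops: pd.DataFrame,
    peaks: list[GenomicInterval],
    probe_map: ProbeMap,
) -> np.ndarray:
    """Per-loop flag: does any peak overlap either extended anchor (>=1 bp)?"""
    starts = np.array([p.start for p in sorted(peaks)])
    ends = np.array([p.end for p in sorted(peaks)])
    cache: dict[str, bool] = {}

    def bound(pid: str) -> bool:
        if pid not in cache:
            ext = extend_anchor(pid, probe_map).extended
            # overlap >= 1 bp in half-open coords: peak.start < ext.end and ext.start < peak.end
            cache[pid] = bool(np.any((starts < ext.end) & (ends > ext.start)))
        return cache[pid]

    if len(peaks) == 0:
        return np.zeros(len(loops), dtype=bool)
    return np.array(
        [bound(f) or bound(r) for f, r in zip(loops["fwd_id"], loops["rev_id"])]
    )


@dataclass
class EnrichmentResult:
    protein: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: significant, background
    odds_ratio: float
    p_value: float
    bound_fraction_significant: float
    bound_fraction_background: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else float("inf")


def fisher_enrichment(
    significant_bound: np.ndarray,
    background_bound: np.ndarray,
    protein: str = "",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher exact test of binding among significant vs background loops.

    The 2x2 table is (significant, background) x (bound, unbound).  The odds
    ratio uses the Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    sig = np.asarray(significant_bound, dtype=bool)
    bg = np.asarray(background_bound, dtype=bool)
    if sig.size == 0 or bg.size == 0:
        raise ValueError("significant and background sets must be non-empty")
    a, b = int(sig.sum()), int((~sig).sum())
    c, d = int(bg.sum()), int((~bg).sum())
    _or, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        protein=protein,
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p_value=float(p),
        bound_fraction_significant=a / (a + b),
        bound_fraction_background=c / (c + d),
    )


def enhancer_loop_enrichment(
    enhancer_bound: np.ndarray,
    background_bound: np.ndarray,
    protein: str = "",
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher enrichment with the significant set restricted to
    enhancer-involving loops."""
    if np.asarray(enhancer_bound).size == 0:
        raise ValueError("enhancer-involving loop set is empty")
    return fisher_enrichment(enhancer_bound, background_bound, protein, alternative)


def pairwise_cooccupancy(binding: dict[str, np.ndarray]) -> pd.DataFrame:
    """Co-occupancy percentages between proteins at loop anchors.

    Cell (P, Q) = 100 * |bound by P and Q| / |bound by P|; the diagonal is
    100 by construction and the matrix is not symmetric.  Rows with no
    P-bound loops are NaN.
    """
    if len(binding) < 2:
        raise ValueError("need flags for at least 2 proteins")
    names = list(binding)
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for p in names:
        bp = np.asarray(binding[p], dtype=bool)
        denom = bp.sum()
        for q in names:
            bq = np.asarray(binding[q], dtype=bool)
            out.loc[p, q] = 100.0 * (bp & bq).sum() / denom if denom else float("nan")
    return out
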