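"""Regulatory annotation of the consensus interactome.

Enhancers are operationally defined as merged H3K4me1 and H3K27ac peak
regions lying within 2 kb end-to-end of each other (each mark pre-merged at
5 kb); closely spaced enhancers (< 10 kb end-to-end) form clusters.
Consensus loops are classified by promoter content (TSS within 5 kb of an
anchor fragment), linked into an enhancer-promoter network (10 kb windows),
labelled intra- vs inter-TAD, and summarized as distance-scaling curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, ProbeMap
from .tad_calling import TadSet


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """End-to-end gap between two intervals; 0 when they touch or overlap."""
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def _point_gap(interval: GenomicInterval, pos: int) -> int:
    """Distance from a point to an interval; 0 when the point lies inside."""
    if pos < interval.start:
        return interval.start - pos
    if pos >= interval.end:
        return pos - interval.end
    return 0


def merge_peaks(peaks: list[GenomicInterval], max_gap: int = 5_000) -> list[GenomicInterval]:
    """Transitively merge intervals with end-to-end gap <= ``max_gap``.

    Overlapping intervals count as gap 0.  Output is sorted and pairwise
    farther than ``max_gap`` apart; the operation is idempotent and
    input-order invariant.
    """
    if not peaks:
        return []
    peaks = sorted(peaks)
    merged = [peaks[0]]
    for p in peaks[1:]:
        last = merged[-1]
        if p.chrom == last.chrom and p.start - last.end <= max_gap:
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, p.end), last.name
            )
        else:
            merged.append(p)
    return merged


@dataclass
class Enhancer:
    """A putative active enhancer: paired H3K4me1/H3K27ac signature."""

    interval: GenomicInterval
    enhancer_id: str
    k4me1: GenomicInterval
    k27ac: GenomicInterval
    cluster_id: str | None = None


def call_enhancers(
    k4me1: list[GenomicInterval],
    k27ac: list[GenomicInterval],
    *,
    pair_gap: int = 2_000,
    premerge_gap: int = 5_000,
) -> list[Enhancer]:
    """Enhancers = merged H3K4me1 / merged H3K27ac pairs within 2 kb.

    Each mark set is first merged at ``premerge_gap``; every cross-mark pair
    with end-to-end distance <= ``pair_gap`` yields a candidate whose
    interval is the union span of the pair; overlapping candidates are then
    unioned and ids E1..En assigned in genomic order.  Enhancers near gene
    promoters are deliberately not excluded.
    """
    m1 = merge_peaks(k4me1, premerge_gap)
    m2 = merge_peaks(k27ac, premerge_gap)
    candidates: list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]] = []
    for a in m1:
        for b in m2:
            if a.chrom == b.chrom and _gap(a, b) <= pair_gap:
                union = GenomicInterval(
                    a.chrom, min(a.start, b.start), max(a.end, b.end)
                )
                candidates.append((union, a, b))
    if not candidates:
        return []
    candidates.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    groups: list[list[tuple[GenomicInterval, GenomicInterval, GenomicInterval]]] = [
        [candidates[0]]
    ]
    for c in candidates[1:]:
        last_union = groups[-1][0][0]
        span_end = max(u.end for u, _, _ in groups[-1])
        if c[0].chrom == last_union.chrom and c[0].start < span_end:
            groups[-1].append(c)
        else:
            groups.append([c])
    enhancers = []
    for k, grp in enumerate(groups, start=1):
        start = min(u.start for u, _, _ in grp)
        end = max(u.end for u, _, _ in grp)
        chrom = grp[0][0].chrom
        enhancers.append(
            Enhancer(
                interval=GenomicInterval(chrom, start, end, f"E{k}"),
                enhancer_id=f"E{k}",
                k4me1=grp[0][1],
                k27ac=grp[0][2],
            )
        )
    return enhancers


def cluster_enhancers(
    enhancers: list[Enhancer], max_gap: int = 10_000
) -> dict[str, str]:
    """Cluster enhancers closer than ``max_gap`` end-to-end (strict <).

    Returns enhancer_id -> cluster label; clustered enhancers share a label
    like ``E2/E3``; singletons keep their own id.  Assignments are also
    written onto the Enhancer objects.
    """
    if not enhancers:
        return {}
    enhancers = sorted(enhancers, key=lambda e: (e.interval.chrom, e.interval.start))
    groups: list[list[Enhancer]] = [[enhancers[0]]]
    for e in enhancers[1:]:
        prev = groups[-1][-1]
        if (
            e.interval.chrom == prev.interval.chrom
            and _gap(prev.interval, e.interval) < max_gap
        ):
            groups[-1].append(e)
        else:
            groups.append([e])
    assignment: dict[str, str] = {}
    for grp in groups:
        if len(grp) == 1:
            label = grp[0].enhancer_id
        else:
            ids = [e.enhancer_id for e in grp]
            label = f"{ids[0]}-{ids[-1]}" if len(ids) > 2 else "/".join(ids)
        for e in grp:
            e.cluster_id = label
            assignment[e.enhancer_id] = label
    return assignment


# ---------------------------------------------------------------------------
# promoter classification

def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_by_promoter(
    loops: pd.DataFrame,
    probe_map: ProbeMap,
    tss_table: pd.DataFrame,
    window: int = 5_000,
) -> tuple[dict[str, int], pd.Series]:
    """Classify loops as promoter-promoter (PP), promoter-none (PN) or NN.

    An anchor is a promoter anchor iff any TSS lies within ``window`` bp of
    its restriction-fragment interval (distance 0 when the TSS is inside).
    Returns class counts and the per-loop label series.
    """
    tss = np.sort(tss_table["tss"].to_numpy())

    def is_promoter(pid: str) -> bool:
        frag = probe_map[pid].fragment
        i = np.searchsorted(tss, frag.start)
        for j in (i - 1, i, i + 1):
            if 0 <= j < tss.size and _point_gap(frag, int(tss[j])) <= window:
                return True
        return False

    cache: dict[str, bool] = {}

    def anchor(pid: str) -> bool:
        if pid not in cache:
            cache[pid] = is_promoter(pid)
        return cache[pid]

    labels = []
    for fwd, rev in zip(loops["fwd_id"], loops["rev_id"]):
        a, b = anchor(fwd), anchor(rev)
        labels.append("PP" if a and b else ("NN" if not a and not b else "PN"))
    labels = pd.Series(labels, index=loops.index, name="class")
    counts = {c: int((labels == c).sum()) for c in ("PP", "PN", "NN")}
    return counts, labels


def promoter_class_percentages(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: _round2(100.0 * v / total) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# enhancer-promoter network

def assign_enhancer_network(
    loops: pd.DataFrame,
    enhancers: list[Enhancer],
    probe_map: ProbeMap,
    tss_table: pd.DataFrame,
    tads: TadSet | None = None,
    enhancer_window: int = 10_000,
    tss_window: int = 10_000,
) -> pd.DataFrame:
    """Assign loops to enhancers (or clusters) and target TSSs.

    A loop involves an enhancer iff one anchor fragment lies within
    ``enhancer_window`` of the enhancer interval; the opposite anchor's
    target is the closest TSS within ``tss_window``, else "non-promoter".
    One output row per (loop, enhancer unit); clustered enhancers are
    reported under their cluster label.
    """
    tss_sorted = tss_table.sort_values("tss")
    tss_pos = tss_sorted["tss"].to_numpy()
    tss_ids = tss_sorted["gene_id"].to_numpy()

    def closest_tss(frag: GenomicInterval) -> str | None:
        if tss_pos.size == 0:
            return None
        gaps = np.array([_point_gap(frag, int(t)) for t in tss_pos])
        k = int(np.argmin(gaps))
        return str(tss_ids[k]) if gaps[k] <= tss_window else None

    rows = []
    for idx, loop in loops.iterrows():
        frag_f = probe_map[loop["fwd_id"]].fragment
        frag_r = probe_map[loop["rev_id"]].fragment
        for enh in enhancers:
            unit = enh.cluster_id or enh.enhancer_id
            for near, far in ((frag_f, frag_r), (frag_r, frag_f)):
                if near.chrom != enh.interval.chrom:
                    continue
                if _gap(near, enh.interval) <= enhancer_window:
                    target = closest_tss(far)
                    tad_label = ""
                    if tads is not None:
                        ta = tads.tad_index_of((near.start + near.end) // 2)
                        tb = tads.tad_index_of((far.start + far.end) // 2)
                        tad_label = "intra" if ta is not None and ta == tb else "inter"
                    rows.append(
                        {
                            "enhancer_unit": unit,
                            "enhancer_id": enh.enhancer_id,
                            "loop_index": idx,
                            "fwd_id": loop["fwd_id"],
                            "rev_id": loop["rev_id"],
                            "target_gene": target if target else "non-promoter",
                            "tad_label": tad_label,
                        }
                    )
                    break  # one row per (loop, enhancer)
    df = pd.DataFrame(
        rows,
        columns=[
            "enhancer_unit", "enhancer_id", "loop_index", "fwd_id", "rev_id",
            "target_gene", "tad_label",
        ],
    )
    # a loop touching two enhancers of the same cluster is one network edge
    df = df.drop_duplicates(subset=["enhancer_unit", "loop_index"]).reset_index(drop=True)
    return df


def enhancer_involvement_summary(network: pd.DataFrame, n_loops_total: int) -> dict:
    """Headline percentages of enhancer involvement (floored to integers).

    ``pct_loops_enhancer`` = unique loops touching any enhancer over all
    consensus loops; ``pct_rows_promoter_target`` = network rows whose
    opposite anchor has a promoter target over all rows (the per-(loop,
    enhancer-unit) accounting).
    """
    n_involving = int(network["loop_index"].nunique())
    n_rows = int(len(network))
    n_to_promoter = int((network["target_gene"] != "non-promoter").sum())
    return {
        "n_loops_total": n_loops_total,
        "n_loops_enhancer": n_involving,
        "pct_loops_enhancer": math.floor(100.0 * n_involving / n_loops_total)
        if n_loops_total else 0,
        "n_rows": n_rows,
        "n_rows_promoter_target": n_to_promoter,
        "pct_rows_promoter_target": math.floor(100.0 * n_to_promoter / n_rows)
        if n_rows else 0,
    }


# ---------------------------------------------------------------------------
# TAD membership

def label_intra_inter_tad(
    loops: pd.DataFrame, tads: TadSet, probe_map: ProbeMap
) -> tuple[pd.Series, dict]:
    """Label each loop intra- or inter-TAD by anchor-fragment midpoints."""
    labels = []
    for fwd, rev in zip(loops["fwd_id"], loops["rev_id"]):
        ta = tads.tad_index_of(probe_map[fwd].midpoint)
        tb = tads.tad_index_of(probe_map[rev].midpoint)
        if ta is None or tb is None:
            labels.append("outside")
        else:
            labels.append("intra" if ta == tb else "inter")
    labels = pd.Series(labels, index=loops.index, name="tad_label")
    n_out = int((labels == "outside").sum())
    if n_out:
        warnings.warn(f"{n_out} loops anchor outside all TADs; excluded from percentages")
    summary = intra_inter_summary(
        int((labels == "intra").sum()), int((labels == "inter").sum())
    )
    summary["n_outside"] = n_out
    return labels, summary


def intra_inter_summary(n_intra: int, n_inter: int) -> dict:
    """Counts and two-decimal percentages of intra- vs inter-TAD loops."""
    total = n_intra + n_inter
    return {
        "n_intra": n_intra,
        "n_inter": n_inter,
        "pct_intra": _round2(100.0 * n_intra / total) if total else float("nan"),
        "pct_inter": _round2(100.0 * n_inter / total) if total else float("nan"),
    }


# ---------------------------------------------------------------------------
# scaling curves and locus/TAD-span counting

def scaling_curve(
    distances: np.ndarray,
    values: np.ndarray,
    labels: pd.Series | np.ndarray,
    n_bins: int = 15,
) -> pd.DataFrame:
    """Mean signal per log-spaced distance bin, per interaction class."""
    distances = np.asarray(distances, dtype=float)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if distances.size == 0:
        return pd.DataFrame(columns=["class", "bin_lo", "bin_hi", "mean_value", "n"])
    lo, hi = distances.min(), distances.max()
    edges = (
        np.geomspace(max(lo, 1.0), hi, n_bins + 1)
        if hi > lo
        else np.array([lo, hi + 1.0])
    )
    edges[-1] = np.nextafter(edges[-1], np.inf)
    rows = []
    for cls in np.unique(labels):
        sel = labels == cls
        which = np.clip(np.digitize(distances[sel], edges) - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            inbin = which == b
            if not np.any(inbin):
                continue
            rows.append(
                {
                    "class": cls,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "mean_value": float(values[sel][inbin].mean()),
                    "n": int(inbin.sum()),
                }
            )
    return pd.DataFrame(rows)


def count_tads_spanned(
    locus: GenomicInterval, tad_map: list[GenomicInterval]
) -> int:
    """Number of TADs a locus overlaps by at least 1 bp."""
    n = sum(1 for tad in tad_map if tad.overlaps(locus))
    if not any(tad.chrom == locus.chrom for tad in tad_map):
        warnings.warn(f"no TADs on chromosome {locus.chrom}")
    return n
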