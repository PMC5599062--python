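"""Ground-truth-known synthetic 5C data.

Emulates the statistical structure of a single ~5 Mb locus interrogated by an
alternating forward/reverse 5C probe design: power-law contact-distance
decay, a block-diagonal TAD structure with gene-rich/gene-poor contrast (plus
an optional long-range contact between two gene-poor domains), planted
looping interactions, multiplicative per-probe efficiency biases, rare
extreme "singleton" spikes, corrupted probes, and independent Poisson
counting noise per replicate library.  Every planted feature is recorded in a
:class:`GroundTruth` so downstream QC and calling stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FORWARD, REVERSE, ContactMatrix, GenomicInterval, Probe, ProbeMap


@dataclass(frozen=True)
class RegionSpec:
    """The simulated locus (0-based half-open)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.label or "region")


@dataclass
class TadLayout:
    """Planted domain structure: boundary midpoints and per-TAD classes.

    ``intra_boost`` multiplies contacts within a TAD; ``cross_pair_boost``
    optionally boosts contacts between a specific TAD pair, emulating
    compartment-like association of two gene-poor domains.
    """

    boundaries: list[int]
    classes: list[str]
    intra_boost: float = 3.0
    cross_pair_boost: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if sorted(self.boundaries) != list(self.boundaries) or len(
            set(self.boundaries)
        ) != len(self.boundaries):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.classes) != len(self.boundaries) + 1:
            raise ValueError("need one class per TAD (boundaries + 1)")
        if self.intra_boost < 1:
            raise ValueError("intra_boost must be >= 1")

    def validate_region(self, region: RegionSpec) -> None:
        for b in self.boundaries:
            if not (region.start < b < region.end):
                raise ValueError(f"boundary {b} outside region")

    def tad_intervals(self, region: RegionSpec) -> list[GenomicInterval]:
        self.validate_region(region)
        edges = [region.start, *self.boundaries, region.end]
        return [
            GenomicInterval(region.chrom, a, b, f"TAD{i + 1}")
            for i, (a, b) in enumerate(zip(edges, edges[1:]))
        ]

    def tad_of(self, positions: np.ndarray, region: RegionSpec) -> np.ndarray:
        """TAD index (0-based) containing each position."""
        return np.searchsorted(np.asarray(self.boundaries), positions, side="right")


@dataclass(frozen=True)
class PlantedLoop:
    """A ground-truth looping interaction on an interrogated pair.

    Indices refer to the forward / reverse probe lists of the ProbeMap.
    """

    forward_probe_index: int
    reverse_probe_index: int
    fold_enrichment: float

    def __post_init__(self):
        if self.fold_enrichment <= 1:
            raise ValueError("fold_enrichment must be > 1")


@dataclass
class SimulationConfig:
    """Noise and scale parameters of the simulated libraries.

    ``depth`` is the expected total count per library; ``decay_exponent`` the
    power-law slope of contact frequency vs genomic distance;
    ``probe_bias_sd`` the SD of the log-normal per-probe multiplicative bias;
    ``singleton_rate`` is the per-cell probability of an extreme spike: a
    PCR/ligation jackpot whose count is ``spike_fold`` times the larger of
    the cell's expectation and the library-average cell signal, so a spike is
    extreme even in sparse long-distance cells; ``bad_probe_count`` probes
    per replicate get their profile distance-shuffled.
    """

    decay_exponent: float = -1.0
    probe_bias_sd: float = 0.3
    singleton_rate: float = 0.001
    bad_probe_count: int = 4
    depth: float = 1e6
    spike_fold: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.singleton_rate < 0.01:
            raise ValueError("singleton_rate must be in [0, 0.01)")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")


@dataclass
class GroundTruth:
    """Everything planted into a simulated replicate set."""

    loops: list[PlantedLoop]
    loop_pairs: list[tuple[str, str]]
    bad_probes: list[list[str]]  # per replicate, probe ids
    singletons: list[list[tuple[str, str]]]  # per replicate, (fwd_id, rev_id)
    expected_biasfree: np.ndarray  # depth-scaled expectation without biases
    fwd_bias: np.ndarray
    rev_bias: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "loops": [
                {
                    "forward_probe_index": l.forward_probe_index,
                    "reverse_probe_index": l.reverse_probe_index,
                    "fold_enrichment": l.fold_enrichment,
                }
                for l in self.loops
            ],
            "loop_pairs": [list(p) for p in self.loop_pairs],
            "bad_probes": self.bad_probes,
            "singletons": [[list(c) for c in rep] for rep in self.singletons],
        }


# ---------------------------------------------------------------------------
# default study conditions: 5.3 Mb locus, 763 alternating probes, 7 TADs

def default_region() -> RegionSpec:
    return RegionSpec("chr3", 89_900_000, 95_200_000, "EDC")


def default_layout() -> TadLayout:
    start = 89_900_000
    offsets = [800_000, 1_550_000, 2_300_000, 3_000_000, 3_750_000, 4_550_000]
    return TadLayout(
        boundaries=[start + o for o in offsets],
        classes=[
            "gene_rich", "gene_poor", "gene_rich", "gene_rich",
            "gene_poor", "gene_rich", "gene_rich",
        ],
        intra_boost=3.0,
        cross_pair_boost={(1, 4): 2.0},
    )


def make_probe_map(
    region: RegionSpec,
    mean_fragment_kb: float = 6.95,
    seed: int = 0,
    *,
    exclude_fraction: float = 0.0,
    phase: str = REVERSE,
    length_jitter: float = 0.3,
) -> ProbeMap:
    """Tile the region with restriction fragments and alternate probes.

    Fragments tile the region without gaps with lengths jittered around
    ``mean_fragment_kb``; probe orientation alternates by fragment parity
    starting with ``phase``; a fraction of fragments carries no probe,
    emulating repeat regions where no unique probe could be designed.
    """
    if mean_fragment_kb <= 0:
        raise ValueError("mean_fragment_kb must be > 0")
    if phase not in (FORWARD, REVERSE):
        raise ValueError(f"phase must be {FORWARD!r} or {REVERSE!r}")
    mean_bp = mean_fragment_kb * 1000.0
    n_frag = int(round(region.length / mean_bp))
    if n_frag < 1:
        raise ValueError("region shorter than one fragment")
    rng = np.random.default_rng(seed)
    weights = rng.uniform(1 - length_jitter, 1 + length_jitter, n_frag)
    edges = np.concatenate([[0.0], np.cumsum(weights)])
    edges = region.start + np.round(edges / edges[-1] * region.length).astype(int)
    edges = np.unique(edges)  # guard against zero-length fragments
    n_frag = len(edges) - 1

    keep = rng.random(n_frag) >= exclude_fraction
    orientations = [FORWARD, REVERSE] if phase == FORWARD else [REVERSE, FORWARD]
    probes: list[Probe] = []
    n_f = n_r = 0
    for k in range(n_frag):
        if not keep[k]:
            continue
        orient = orientations[k % 2]
        if orient == FORWARD:
            n_f += 1
            pid = f"F{n_f:04d}"
        else:
            n_r += 1
            pid = f"R{n_r:04d}"
        probes.append(Probe(pid, orient, region.chrom, int(edges[k]), int(edges[k + 1])))
    return ProbeMap(probes)


def _expected_grid(
    probe_map: ProbeMap,
    layout: TadLayout | None,
    loops: list[PlantedLoop],
    config: SimulationConfig,
    region: RegionSpec,
) -> np.ndarray:
    d = probe_map.distance_grid()
    d = np.maximum(d, 1.0)
    expected = d ** config.decay_exponent
    if layout is not None:
        ft = layout.tad_of(probe_map.fwd_mids, region)
        rt = layout.tad_of(probe_map.rev_mids, region)
        gain = np.ones_like(expected)
        same = ft[:, None] == rt[None, :]
        gain[same] = layout.intra_boost
        for (a, b), g in layout.cross_pair_boost.items():
            pair = (ft[:, None] == a) & (rt[None, :] == b)
            pair |= (ft[:, None] == b) & (rt[None, :] == a)
            gain[pair & ~same] = g
        expected = expected * gain
    for loop in loops:
        expected[loop.forward_probe_index, loop.reverse_probe_index] *= (
            loop.fold_enrichment
        )
    total = expected.sum()
    if total > 0 and config.depth > 0:
        expected *= config.depth / total
    else:
        expected = np.zeros_like(expected)
    return expected


def simulate_contact_matrices(
    probe_map: ProbeMap,
    layout: TadLayout | None,
    loops: list[PlantedLoop],
    config: SimulationConfig,
    n_replicates: int = 2,
    region: RegionSpec | None = None,
) -> tuple[list[ContactMatrix], GroundTruth]:
    """Draw replicate count matrices around a structured expectation.

    The expected signal of pair (i, j) is depth-scaled
    ``distance^decay_exponent`` times the TAD/loop gains and both probe
    biases; each replicate draws independent Poisson counts, then injects
    singleton spikes and distance-shuffled "bad probe" profiles, all recorded
    in the returned :class:`GroundTruth`.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if region is None:
        span = probe_map.span
        region = RegionSpec(span.chrom, span.start, span.end)
    n_fwd, n_rev = len(probe_map.forward), len(probe_map.reverse)
    for loop in loops:
        if not (0 <= loop.forward_probe_index < n_fwd) or not (
            0 <= loop.reverse_probe_index < n_rev
        ):
            raise ValueError(f"planted loop {loop} references a probe-less fragment")

    rng = np.random.default_rng(config.seed)
    base = _expected_grid(probe_map, layout, loops, config, region)

    if config.probe_bias_sd > 0:
        mu = -0.5 * config.probe_bias_sd ** 2  # unit-mean log-normal
        fwd_bias = rng.lognormal(mu, config.probe_bias_sd, n_fwd)
        rev_bias = rng.lognormal(mu, config.probe_bias_sd, n_rev)
    else:
        fwd_bias = np.ones(n_fwd)
        rev_bias = np.ones(n_rev)
    expected = base * fwd_bias[:, None] * rev_bias[None, :]

    all_probe_ids = [p.probe_id for p in probe_map.probes]
    matrices: list[ContactMatrix] = []
    bad_per_rep: list[list[str]] = []
    singles_per_rep: list[list[tuple[str, str]]] = []
    for r in range(n_replicates):
        counts = rng.poisson(expected).astype(float)

        bad_ids = sorted(
            rng.choice(all_probe_ids, size=min(config.bad_probe_count, len(all_probe_ids)), replace=False)
        ) if config.bad_probe_count else []
        for pid in bad_ids:
            probe = probe_map[pid]
            if probe.orientation == FORWARD:
                i = probe_map.fwd_index(pid)
                shuffled = rng.permutation(expected[i, :])
                counts[i, :] = rng.poisson(shuffled)
            else:
                j = probe_map.rev_index(pid)
                shuffled = rng.permutation(expected[:, j])
                counts[:, j] = rng.poisson(shuffled)

        singles: list[tuple[str, str]] = []
        if config.singleton_rate > 0 and config.depth > 0:
            hit = rng.random(expected.shape) < config.singleton_rate
            mean_cell = expected.mean()
            for i, j in zip(*np.nonzero(hit)):
                level = max(expected[i, j], mean_cell)
                counts[i, j] = rng.poisson(level * config.spike_fold)
                singles.append(
                    (probe_map.forward[i].probe_id, probe_map.reverse[j].probe_id)
                )

        matrices.append(
            ContactMatrix(probe_map, counts, library_label=f"rep{r + 1}")
        )
        bad_per_rep.append(list(bad_ids))
        singles_per_rep.append(singles)

    truth = GroundTruth(
        loops=list(loops),
        loop_pairs=[
            (
                probe_map.forward[l.forward_probe_index].probe_id,
                probe_map.reverse[l.reverse_probe_index].probe_id,
            )
            for l in loops
        ],
        bad_probes=bad_per_rep,
        singletons=singles_per_rep,
        expected_biasfree=base,
        fwd_bias=fwd_bias,
        rev_bias=rev_bias,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# annotations

GENE_RICH_KB_PER_GENE = (21.0, 36.0)
GENE_POOR_KB_PER_GENE = (166.0, 400.0)


def simulate_annotations(
    layout: TadLayout,
    region: RegionSpec,
    seed: int = 0,
    *,
    probe_map: ProbeMap | None = None,
    loops: list[PlantedLoop] | None = None,
    enhancers_per_rich_tad: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[GenomicInterval]]]:
    """Generate a TSS table and histone-mark / protein peak sets.

    Gene-rich TADs get one gene per 21-36 kb, gene-poor TADs one per
    166-400 kb.  Paired H3K4me1/H3K27ac peaks (the enhancer signature) are
    placed only in gene-rich TADs; CTCF/Rad21/Brg1 peaks preferentially in
    gene-rich TADs and, when a probe map and planted loops are supplied, at
    the planted loop anchors.
    """
    rng = np.random.default_rng(seed)
    tads = layout.tad_intervals(region)

    genes = []
    kb_per_gene_drawn = []
    for t, (tad, cls) in enumerate(zip(tads, layout.classes)):
        lo, hi = GENE_RICH_KB_PER_GENE if cls == "gene_rich" else GENE_POOR_KB_PER_GENE
        kbper = rng.uniform(lo, hi)
        kb_per_gene_drawn.append(kbper)
        n = max(1, int(round(len(tad) / 1000.0 / kbper)))
        tss = np.sort(rng.integers(tad.start, tad.end, n))
        for k, pos in enumerate(tss):
            genes.append(
                {
                    "gene_id": f"g{t + 1}_{k + 1}",
                    "chrom": region.chrom,
                    "tss": int(pos),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "tad": tad.name,
                }
            )
    genes_df = pd.DataFrame(genes).sort_values("tss", kind="mergesort").reset_index(drop=True)
    genes_df.attrs["kb_per_gene_drawn"] = kb_per_gene_drawn

    k4me1: list[GenomicInterval] = []
    k27ac: list[GenomicInterval] = []
    for tad, cls in zip(tads, layout.classes):
        if cls != "gene_rich":
            continue
        n_enh = max(1, enhancers_per_rich_tad + int(rng.integers(-1, 2)))
        for _ in range(n_enh):
            x = int(rng.integers(tad.start, tad.end - 4000))
            k4me1.append(GenomicInterval(region.chrom, x, x + 1500))
            k27ac.append(GenomicInterval(region.chrom, x + 2000, x + 3000))
        # decoy mark without its partner: no enhancer signature
        x = int(rng.integers(tad.start, tad.end - 2000))
        k4me1.append(GenomicInterval(region.chrom, x, x + 1000))

    proteins: dict[str, list[GenomicInterval]] = {"CTCF": [], "Rad21": [], "Brg1": []}
    if probe_map is not None and loops:
        for loop in loops:
            for probe in (
                probe_map.forward[loop.forward_probe_index],
                probe_map.reverse[loop.reverse_probe_index],
            ):
                mid = probe.midpoint
                for name in proteins:
                    if rng.random() < 0.8:
                        proteins[name].append(
                            GenomicInterval(region.chrom, mid - 250, mid + 250)
                        )
    for tad, cls in zip(tads, layout.classes):
        lam = 8 if cls == "gene_rich" else 1
        for name in proteins:
            for _ in range(rng.poisson(lam)):
                x = int(rng.integers(tad.start, tad.end - 500))
                proteins[name].append(GenomicInterval(region.chrom, x, x + 500))

    peaks = {"H3K4me1": sorted(k4me1), "H3K27ac": sorted(k27ac)}
    peaks.update({k: sorted(v) for k, v in proteins.items()})
    return genes_df, peaks
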