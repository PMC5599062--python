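"""Core data containers and text formats shared by every pipeline stage.

5C interrogates ligation junctions between *forward* and *reverse* probes
placed on alternating restriction fragments; only forward-reverse probe pairs
produce a measurable count, so a contact matrix is a (forward x reverse) grid
rather than a symmetric fragment-by-fragment map.

All internal coordinates are 0-based half-open.  BED is read/written natively
in that convention; TSV emitters carry a header comment stating it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FORWARD = "forward"
REVERSE = "reverse"

_COORD_COMMENT = "# coordinates: 0-based, half-open"


class FormatError(ValueError):
    """Malformed input file; carries a line number when one is known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.name or ''} has start >= end "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Probe:
    """A 5C probe and the restriction fragment it interrogates."""

    probe_id: str
    orientation: str  # forward | reverse
    chrom: str
    frag_start: int
    frag_end: int

    def __post_init__(self):
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.frag_start >= self.frag_end:
            raise ValueError(f"probe {self.probe_id}: frag_start >= frag_end")

    @property
    def midpoint(self) -> int:
        return (self.frag_start + self.frag_end) // 2

    @property
    def fragment(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.frag_start, self.frag_end, self.probe_id)


class ProbeMap:
    """Ordered forward/reverse probe set defining the interrogated pairs.

    Probes are kept in genomic order; fragments must not overlap.  The
    forward and reverse subsets index the rows and columns of every
    :class:`ContactMatrix` built on this map.
    """

    def __init__(self, probes: list[Probe]):
        probes = sorted(probes, key=lambda p: (p.chrom, p.frag_start))
        for a, b in zip(probes, probes[1:]):
            if a.chrom == b.chrom and b.frag_start < a.frag_end:
                raise ValueError(
                    f"overlapping fragments: {a.probe_id} and {b.probe_id}"
                )
        self.probes = probes
        self.forward = [p for p in probes if p.orientation == FORWARD]
        self.reverse = [p for p in probes if p.orientation == REVERSE]
        self._by_id = {p.probe_id: p for p in probes}
        if len(self._by_id) != len(probes):
            raise ValueError("duplicate probe ids")
        self._fwd_index = {p.probe_id: i for i, p in enumerate(self.forward)}
        self._rev_index = {p.probe_id: i for i, p in enumerate(self.reverse)}
        self.fwd_mids = np.array([p.midpoint for p in self.forward], dtype=float)
        self.rev_mids = np.array([p.midpoint for p in self.reverse], dtype=float)

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, probe_id: str) -> Probe:
        return self._by_id[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def fwd_index(self, probe_id: str) -> int:
        return self._fwd_index[probe_id]

    def rev_index(self, probe_id: str) -> int:
        return self._rev_index[probe_id]

    @property
    def span(self) -> GenomicInterval:
        first, last = self.probes[0], self.probes[-1]
        return GenomicInterval(first.chrom, first.frag_start, last.frag_end, "span")

    def distance_grid(self) -> np.ndarray:
        """|forward midpoint - reverse midpoint| for every interrogated pair."""
        return np.abs(self.fwd_mids[:, None] - self.rev_mids[None, :])

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeMap) and self.probes == other.probes


def count_interrogated_pairs(probe_map: ProbeMap) -> int:
    """Number of forward-reverse probe pairs the design can measure.

    Only forward-reverse pairs yield true 5C counts, so the pool interrogates
    exactly ``len(forward) * len(reverse)`` pairwise contacts.
    """
    return len(probe_map.forward) * len(probe_map.reverse)


class ContactMatrix:
    """Forward x reverse contact signal with per-cell and per-probe masks.

    ``values`` holds raw counts (integral) or normalized signal (float);
    masks record QC removals.  A masked probe implies all of its cells are
    masked; the combined view is :attr:`mask`.
    """

    def __init__(
        self,
        probe_map: ProbeMap,
        values: np.ndarray,
        cell_mask: np.ndarray | None = None,
        fwd_probe_mask: np.ndarray | None = None,
        rev_probe_mask: np.ndarray | None = None,
        library_label: str = "",
    ):
        n_fwd, n_rev = len(probe_map.forward), len(probe_map.reverse)
        values = np.asarray(values, dtype=float)
        if values.shape != (n_fwd, n_rev):
            raise ValueError(
                f"matrix shape {values.shape} does not match probe map "
                f"({n_fwd} forward x {n_rev} reverse)"
            )
        if np.any(values < 0):
            raise ValueError("negative contact values")
        self.probe_map = probe_map
        self.values = values
        self.cell_mask = (
            np.zeros((n_fwd, n_rev), dtype=bool) if cell_mask is None else np.asarray(cell_mask, bool).copy()
        )
        self.fwd_probe_mask = (
            np.zeros(n_fwd, dtype=bool) if fwd_probe_mask is None else np.asarray(fwd_probe_mask, bool).copy()
        )
        self.rev_probe_mask = (
            np.zeros(n_rev, dtype=bool) if rev_probe_mask is None else np.asarray(rev_probe_mask, bool).copy()
        )
        self.library_label = library_label
        # per-probe multiplicative scales applied by profile normalization;
        # ones for raw matrices.  Used to propagate counting noise.
        self.fwd_scale = np.ones(n_fwd)
        self.rev_scale = np.ones(n_rev)

    @property
    def mask(self) -> np.ndarray:
        """True where a cell is removed (cell-level or via a masked probe)."""
        return (
            self.cell_mask
            | self.fwd_probe_mask[:, None]
            | self.rev_probe_mask[None, :]
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def distance_grid(self) -> np.ndarray:
        return self.probe_map.distance_grid()

    def copy(self) -> "ContactMatrix":
        out = ContactMatrix(
            self.probe_map,
            self.values.copy(),
            self.cell_mask,
            self.fwd_probe_mask,
            self.rev_probe_mask,
            self.library_label,
        )
        out.fwd_scale = self.fwd_scale.copy()
        out.rev_scale = self.rev_scale.copy()
        return out


# ---------------------------------------------------------------------------
# probe tables

_PROBE_COLUMNS = ["probe_id", "orientation", "chrom", "frag_start", "frag_end"]


def read_probe_table(path) -> ProbeMap:
    """Read a probe TSV (probe_id, orientation, chrom, frag_start, frag_end)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing columns: {missing}")
    if df.empty:
        raise FormatError("no probes in probe table")
    probes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            probes.append(
                Probe(
                    row.probe_id,
                    row.orientation,
                    row.chrom,
                    int(row.frag_start),
                    int(row.frag_end),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), line=i) from exc
    try:
        return ProbeMap(probes)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_probe_table(probe_map: ProbeMap, path) -> None:
    df = pd.DataFrame(
        [
            (p.probe_id, p.orientation, p.chrom, p.frag_start, p.frag_end)
            for p in probe_map.probes
        ],
        columns=_PROBE_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contact matrices

def read_matrix(path, probe_map: ProbeMap, library_label: str = "") -> ContactMatrix:
    """Read a contact matrix (pairwise list, or dense grid read-only).

    The canonical dialect is the pairwise TSV ``fwd_probe_id  rev_probe_id
    count``; unlisted forward-reverse pairs are zero and unmasked.  A dense
    grid (reverse probes as columns, forward as rows) is auto-detected.
    Forward-forward or reverse-reverse pairs are rejected: only
    forward-reverse probe pairs are true 5C counts.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError("empty matrix file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] == ["fwd_probe_id", "rev_probe_id"]:
        return _read_pairwise(lines, probe_map, library_label)
    return _read_dense(lines, probe_map, library_label)


def _require_pair(fwd_id: str, rev_id: str, probe_map: ProbeMap, line: int):
    for pid in (fwd_id, rev_id):
        if pid not in probe_map:
            raise FormatError(f"unknown probe id {pid!r}", line=line)
    o1, o2 = probe_map[fwd_id].orientation, probe_map[rev_id].orientation
    if (o1, o2) != (FORWARD, REVERSE):
        raise FormatError(
            f"pair ({fwd_id}, {rev_id}) is {o1}-{o2}; only forward-reverse "
            "probe pairs are interrogated in 5C",
            line=line,
        )


def _read_pairwise(lines, probe_map, library_label) -> ContactMatrix:
    n_fwd, n_rev = len(probe_map.forward), len(probe_map.reverse)
    values = np.zeros((n_fwd, n_rev))
    cell_mask = np.zeros((n_fwd, n_rev), dtype=bool)
    for ln_no, line in enumerate(lines[1:], start=2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError("expected fwd_probe_id, rev_probe_id, count", line=ln_no)
        fwd_id, rev_id, count = parts[0], parts[1], parts[2]
        _require_pair(fwd_id, rev_id, probe_map, ln_no)
        i, j = probe_map.fwd_index(fwd_id), probe_map.rev_index(rev_id)
        if count in ("NA", "nan", ""):
            cell_mask[i, j] = True
            continue
        c = float(count)
        if c < 0:
            raise FormatError(f"negative count {count}", line=ln_no)
        values[i, j] = c
    return ContactMatrix(probe_map, values, cell_mask, library_label=library_label)


def _read_dense(lines, probe_map, library_label) -> ContactMatrix:
    header = lines[0].rstrip("\n").split("\t")
    rev_ids = header[1:]
    n_fwd, n_rev = len(probe_map.forward), len(probe_map.reverse)
    values = np.zeros((n_fwd, n_rev))
    cell_mask = np.zeros((n_fwd, n_rev), dtype=bool)
    for ln_no, line in enumerate(lines[1:], start=2):
        parts = line.rstrip("\n").split("\t")
        fwd_id = parts[0]
        if len(parts) - 1 != len(rev_ids):
            raise FormatError("row length does not match header", line=ln_no)
        for rev_id, cell in zip(rev_ids, parts[1:]):
            _require_pair(fwd_id, rev_id, probe_map, ln_no)
            i, j = probe_map.fwd_index(fwd_id), probe_map.rev_index(rev_id)
            if cell in ("NA", "nan", ""):
                cell_mask[i, j] = True
            else:
                c = float(cell)
                if c < 0:
                    raise FormatError(f"negative count {cell}", line=ln_no)
                values[i, j] = c
    return ContactMatrix(probe_map, values, cell_mask, library_label=library_label)


def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write the pairwise-list dialect; masked cells are written as NA."""
    pm = matrix.probe_map
    with open(path, "w") as fh:
        fh.write(f"# library: {matrix.library_label}\n")
        fh.write("fwd_probe_id\trev_probe_id\tcount\n")
        mask = matrix.mask
        for i, fp in enumerate(pm.forward):
            for j, rp in enumerate(pm.reverse):
                if mask[i, j]:
                    fh.write(f"{fp.probe_id}\t{rp.probe_id}\tNA\n")
                elif matrix.values[i, j] != 0:
                    fh.write(f"{fp.probe_id}\t{rp.probe_id}\t{matrix.values[i, j]:.6g}\n")


# ---------------------------------------------------------------------------
# BED and TSS tables

def read_bed(path) -> list[GenomicInterval]:
    """Read a BED (3+ columns, 0-based half-open); output is sorted."""
    intervals = []
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED needs >= 3 columns", line=ln_no)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"malformed coordinate: {exc}", line=ln_no) from exc
            if start >= end:
                raise FormatError(f"start >= end ({start} >= {end})", line=ln_no)
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            intervals.append(GenomicInterval(parts[0], start, end, name, score))
    return sorted(intervals)


def write_bed(intervals, path, extra_columns: dict[str, list] | None = None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if extra_columns:
                fields += [str(v[k]) for v in extra_columns.values()]
            fh.write("\t".join(fields) + "\n")


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS table (gene_id, chrom, tss, strand) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "chrom", "tss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"TSS table missing columns: {missing}")
    if "strand" not in df.columns:
        df["strand"] = "."
    df = df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    return df


def write_tss_table(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        genes.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loop-call and TAD tables

LOOP_COLUMNS = [
    "fwd_id", "rev_id", "chrom", "fwd_mid", "rev_mid", "distance_bp",
    "obs", "exp", "sd", "z", "p", "q", "replicate_support", "class",
    "enhancer_ids", "target_tss", "tad_label",
]

_LOOP_FLOAT = ["obs", "exp", "sd", "z", "p", "q"]


def write_loop_calls(calls: pd.DataFrame, path) -> None:
    """Write a loop-call TSV; rows ordered genomically, then q ascending."""
    df = calls.copy()
    for col in LOOP_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[LOOP_COLUMNS]
    df = df.sort_values(
        ["chrom", "fwd_mid", "rev_mid", "q"], kind="mergesort"
    ).reset_index(drop=True)
    for col in _LOOP_FLOAT:
        df[col] = df[col].map(lambda v: "" if v == "" or pd.isna(v) else f"{float(v):.6g}")
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_loop_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"fwd_id": str, "rev_id": str})
    for col in _LOOP_FLOAT:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_tads(tads, path) -> None:
    """Write a TadSet as BED with class and kb-per-gene columns."""
    with open(path, "w") as fh:
        for iv, cls, kbg in zip(tads.tads, tads.classes, tads.kb_per_gene):
            kbg_s = "NA" if kbg is None or (isinstance(kbg, float) and np.isnan(kbg)) else f"{kbg:.2f}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{cls}\t{kbg_s}\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
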