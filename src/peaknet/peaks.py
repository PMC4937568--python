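"""Harmonize per-cell-type peak calls into one fixed-width site set.

Each sample's peaks are extended from their midpoints to a uniform width
(default 600 bp).  Within a chromosome, extended peaks are then greedily
merged: as long as some adjacent pair overlaps by more than the bound
(default 200 bp), the most-overlapping such pair (leftmost on ties) is
replaced by a single peak whose active-cell set is the union of the
pair's and whose midpoint is the weighted average of the pair's
midpoints, weighted by the number of cell activations each side carries.
Merging iterates to convergence, so the output provably satisfies the
overlap bound everywhere.

Coordinates are BED-style 0-based half-open throughout.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import one_hot_encode

logger = logging.getLogger(__name__)


class EdgePeakError(ValueError):
    """Extension would leave the chromosome."""


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    cells: frozenset = frozenset()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MergedPeak:
    """A fixed-width site with its active-cell set and activation weight."""

    chrom: str
    start: int
    end: int
    cells: frozenset
    weight: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def activity_vector(self, cell_order) -> np.ndarray:
        return np.array([int(c in self.cells) for c in cell_order], dtype=np.uint8)


@dataclass(frozen=True)
class DatasetSplit:
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def n_sites(self):
        return len(self.train_idx) + len(self.valid_idx) + len(self.test_idx)


def extend_peak(peak: Peak, width: int, chrom_size: int | None = None,
                edge_policy: str = "error") -> Peak:
    """Extend ``peak`` from its midpoint to ``width`` bp.

    ``edge_policy`` governs intervals that would leave the chromosome:
    'error' raises :class:`EdgePeakError`, 'clip' shifts the window back
    inside the bounds (width preserved).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    mid = peak.midpoint
    start = mid - width // 2
    end = start + width
    if start < 0 or (chrom_size is not None and end > chrom_size):
        if edge_policy == "clip":
            if chrom_size is not None and chrom_size < width:
                raise EdgePeakError(
                    f"chromosome {peak.chrom} shorter than width {width}"
                )
            start = max(0, start)
            if chrom_size is not None:
                start = min(start, chrom_size - width)
            end = start + width
        else:
            raise EdgePeakError(
                f"edge peak {peak.chrom}:{peak.start}-{peak.end} "
                f"(extension to {width} bp leaves the chromosome)"
            )
    return Peak(peak.chrom, start, end, peak.cells)


def extend_peaks(peaks, width, chrom_sizes=None, edge_policy="drop"):
    """Extend many peaks; 'drop' silently discards edge peaks (logged)."""
    out, dropped = [], 0
    for p in peaks:
        size = chrom_sizes.get(p.chrom) if chrom_sizes else None
        try:
            out.append(extend_peak(p, width, size,
                                   "clip" if edge_policy == "clip" else "error"))
        except EdgePeakError:
            if edge_policy == "drop":
                dropped += 1
            else:
                raise
    if dropped:
        logger.warning("dropped %d edge peaks", dropped)
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _merge_block(mids, weights, cells, width, overlap_bound):
    """Greedy merge of one chromosome's midpoint-sorted peaks.

    Maintains a doubly linked list over live peaks and a lazy max-heap of
    candidate adjacent pairs keyed by (overlap desc, left midpoint asc).
    After a merger only the two overlaps flanking the new peak change, so
    each merge pushes at most two fresh candidates.
    """
    n = len(mids)
    mids = list(mids)
    weights = list(weights)
    cells = [set(c) for c in cells]
    alive = [True] * n
    version = [0] * n
    prev = list(range(-1, n - 1))
    nxt = list(range(1, n + 1))
    nxt[-1] = -1

    def overlap(i, j):
        return min(width, width - (mids[j] - mids[i]))

    heap = []
    counter = 0

    def push(i, j):
        nonlocal counter
        if i < 0 or j < 0:
            return
        ov = overlap(i, j)
        if ov > overlap_bound:
            heapq.heappush(heap, (-ov, mids[i], counter, i, j, version[i], version[j]))
            counter += 1

    for i in range(n - 1):
        push(i, i + 1)

    while heap:
        neg_ov, _, _, i, j, vi, vj = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or version[i] != vi or version[j] != vj:
            continue
        if nxt[i] != j:
            continue
        if -neg_ov != overlap(i, j):  # stale geometry
            continue
        wi, wj = weights[i], weights[j]
        mids[i] = _round_half_up((wi * mids[i] + wj * mids[j]) / (wi + wj))
        weights[i] = wi + wj
        cells[i] |= cells[j]
        version[i] += 1
        alive[j] = False
        nxt[i] = nxt[j]
        if nxt[j] >= 0:
            prev[nxt[j]] = i
        push(prev[i], i)
        push(i, nxt[i])

    order = [i for i in range(n) if alive[i]]
    return [(mids[i], weights[i], frozenset(cells[i])) for i in order]


def merge_peaks(peaks, width, overlap_bound=200):
    """Greedily merge uniform-width peaks until no adjacent pair overlaps
    by more than ``overlap_bound`` bp.

    ``peaks`` must be grouped by chromosome (each chromosome contiguous)
    and midpoint-sorted within each group, all at width ``width``; a
    violation raises ``ValueError``.  Returns :class:`MergedPeak` sites.
    """
    peaks = list(peaks)
    if not peaks:
        return []
    seen_chroms = set()
    blocks = []  # (chrom, [peak, ...])
    for p in peaks:
        if p.width != width:
            raise ValueError(f"peak {p.chrom}:{p.start}-{p.end} is not {width} bp wide")
        if not blocks or blocks[-1][0] != p.chrom:
            if p.chrom in seen_chroms:
                raise ValueError(f"chromosome {p.chrom} appears in two separate runs")
            seen_chroms.add(p.chrom)
            blocks.append((p.chrom, []))
        elif blocks[-1][1] and p.midpoint < blocks[-1][1][-1].midpoint:
            raise ValueError(f"peaks on {p.chrom} are not midpoint-sorted")
        blocks[-1][1].append(p)

    merged = []
    for chrom, block in blocks:
        result = _merge_block(
            [p.midpoint for p in block],
            [max(1, len(p.cells)) for p in block],
            [p.cells for p in block],
            width,
            overlap_bound,
        )
        for mid, weight, cellset in result:
            start = mid - width // 2
            merged.append(MergedPeak(chrom, start, start + width, cellset, weight))
    return merged


def split_dataset(n_sites, test=0.035, valid=0.034, seed=0) -> DatasetSplit:
    """Uniform random, seed-reproducible train/validation/test split.

    ``test`` and ``valid`` are fractions if < 1, absolute counts
    otherwise; counts exceeding ``n_sites`` are rejected.
    """
    n_test = int(round(test * n_sites)) if 0 <= test < 1 else int(test)
    n_valid = int(round(valid * n_sites)) if 0 <= valid < 1 else int(valid)
    if n_test + n_valid > n_sites:
        raise ValueError("requested split sizes exceed the number of sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_sites)
    return DatasetSplit(
        train_idx=np.sort(perm[n_test + n_valid :]),
        valid_idx=np.sort(perm[n_test : n_test + n_valid]),
        test_idx=np.sort(perm[:n_test]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file-facing helpers


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def read_manifest(path) -> dict:
    """sample_id -> BED path, from a two-column tab-separated manifest."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "path"])
    return dict(zip(df["sample"].astype(str), df["path"]))


def load_sample_peaks(manifest: dict) -> list[Peak]:
    """Read every sample's BED and pool peaks tagged with their sample id."""
    peaks = []
    for sample, path in manifest.items():
        df = read_bed(path)
        for _, row in df.iterrows():
            peaks.append(Peak(str(row["chrom"]), int(row["start"]), int(row["end"]),
                              frozenset([sample])))
    return peaks


def sort_for_merge(peaks) -> list[Peak]:
    return sorted(peaks, key=lambda p: (p.chrom, p.midpoint))


def write_merged_bed(merged, cell_order, path):
    """BED with site name, weight and comma-separated active cells."""
    with open(path, "w") as fh:
        for i, m in enumerate(merged):
            active = ",".join(str(c) for c in cell_order if c in m.cells)
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\tsite_{i:06d}\t{m.weight}\t{active}\n")


def activity_table(merged, cell_order) -> pd.DataFrame:
    mat = np.stack([m.activity_vector(cell_order) for m in merged])
    names = [f"site_{i:06d}" for i in range(len(merged))]
    return pd.DataFrame(mat, index=names, columns=[str(c) for c in cell_order])


def build_dataset(merged, genome, cell_order, dtype=np.float32):
    """Extract and encode sequences for merged sites; build the activity matrix.

    ``genome`` maps chromosome name to sequence (a dict of strings or a
    ``pyfaidx.Fasta``).  Sites overhanging their chromosome are dropped
    with a logged warning.  Returns (X, Y, kept_sites).
    """
    X_rows, Y_rows, kept = [], [], []
    for m in merged:
        if m.chrom not in genome:
            raise KeyError(f"chromosome {m.chrom} absent from the genome")
        if m.start < 0 or m.end > len(genome[m.chrom]):
            logger.warning("dropping %s:%d-%d: outside chromosome bounds",
                           m.chrom, m.start, m.end)
            continue
        seq = str(genome[m.chrom][m.start : m.end])
        X_rows.append(one_hot_encode(seq, dtype=dtype))
        Y_rows.append(m.activity_vector(cell_order))
        kept.append(m)
    if not X_rows:
        return (np.zeros((0, 4, 0), dtype=dtype),
                np.zeros((0, len(cell_order)), dtype=np.uint8), [])
    return np.stack(X_rows), np.stack(Y_rows), kept
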