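"""Blacklist-filtered, RPM-normalized per-strand binned coverage tracks.

Read pairs are assigned to strands by their SAM flags: first-mate flags 16,
83 and 163 go to the forward-strand dataset, flags 0, 99 and 147 to the
reverse-strand dataset, anything else is unassigned.  Each properly-paired
fragment counts once and contributes coverage over its full extent
(extend-reads semantics).  Both strands share a single normalization factor
1e6 / (combined assigned fragments), so forward and reverse tracks are
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .chemistry import AlignmentRecord
from .genome import ParameterError

logger = logging.getLogger(__name__)


class Strand(Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"
    UNASSIGNED = "UNASSIGNED"


_FORWARD_FLAGS = {16, 83, 163}
_REVERSE_FLAGS = {0, 99, 147}


def assign_strand(record) -> Strand:
    """Map a record (or a bare SAM flag integer) to its strand dataset.

    Pure function of the first-mate flag: 16/83/163 -> FORWARD,
    0/99/147 -> REVERSE, any other flag -> UNASSIGNED.
    """
    flag = record.flags_mate1 if isinstance(record, AlignmentRecord) else int(record)
    if flag in _FORWARD_FLAGS:
        return Strand.FORWARD
    if flag in _REVERSE_FLAGS:
        return Strand.REVERSE
    return Strand.UNASSIGNED


@dataclass
class StrandedTrack:
    bin_size: int
    chrom_lengths: dict[str, int]
    forward: dict[str, np.ndarray]
    reverse: dict[str, np.ndarray]
    total_assigned: int

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)


def _bin_means(per_base: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = -(-len(per_base) // bin_size)
    padded = np.zeros(n_bins * bin_size, dtype=np.int64)
    padded[:len(per_base)] = per_base
    return padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader (first three columns) for blacklists and regions."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def build_tracks(records: list[AlignmentRecord], chrom_lengths: dict[str, int],
                 bin_size: int = 5,
                 blacklist: list[tuple[str, int, int]] | None = None,
                 extend_pairs: bool = True) -> StrandedTrack:
    """Bin fragment coverage per strand, zero blacklisted bins, scale to RPM.

    Coverage is per-base fragment occupancy averaged within each bin; with
    ``extend_pairs`` (default) a pair covers pos..pos+fragment_len, otherwise
    only a single point at the fragment start is counted.
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    starts: dict[tuple[str, Strand], list[int]] = {}
    ends: dict[tuple[str, Strand], list[int]] = {}
    total = 0
    for r in records:
        s = assign_strand(r)
        if s is Strand.UNASSIGNED:
            continue
        if r.chrom not in chrom_lengths:
            logger.warning("record on unknown chromosome %s skipped", r.chrom)
            continue
        total += 1
        L = chrom_lengths[r.chrom]
        end = r.pos + (r.fragment_len if extend_pairs else 1)
        if end > L:
            logger.warning("fragment at %s:%d extends beyond chromosome end; "
                           "clipped", r.chrom, r.pos)
            end = L
        key = (r.chrom, s)
        starts.setdefault(key, []).append(min(r.pos, L - 1))
        ends.setdefault(key, []).append(end)

    scale = 1e6 / total if total else 0.0
    forward, reverse = {}, {}
    for chrom, L in chrom_lengths.items():
        for strand, dest in ((Strand.FORWARD, forward), (Strand.REVERSE, reverse)):
            diff = np.zeros(L + 1, dtype=np.int64)
            key = (chrom, strand)
            if key in starts:
                np.add.at(diff, np.asarray(starts[key]), 1)
                np.add.at(diff, np.asarray(ends[key]), -1)
            per_base = np.cumsum(diff[:-1])
            dest[chrom] = _bin_means(per_base, bin_size) * scale
    if blacklist:
        for chrom, bstart, bend in blacklist:
            if chrom not in chrom_lengths:
                continue
            lo, hi = bstart // bin_size, -(-bend // bin_size)
            forward[chrom][lo:hi] = 0.0
            reverse[chrom][lo:hi] = 0.0
    return StrandedTrack(bin_size, dict(chrom_lengths), forward, reverse, total)


def composite_track(track: StrandedTrack) -> dict[str, np.ndarray]:
    """Strand-summed ('composite') signal, the MapR-style view."""
    return {c: track.forward[c] + track.reverse[c] for c in track.forward}


def region_mean_density(arrays: dict[str, np.ndarray], bin_size: int,
                        regions: list[tuple[str, int, int]]) -> np.ndarray:
    """Mean binned signal per region (the per-region 'read density')."""
    out = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        arr = arrays[chrom]
        lo = max(0, start // bin_size)
        hi = min(len(arr), -(-end // bin_size))
        out[i] = arr[lo:hi].mean() if hi > lo else 0.0
    return out


def track_correlation(a: dict[str, np.ndarray], b: dict[str, np.ndarray],
                      regions: list[tuple[str, int, int]] | None = None,
                      bin_size: int | None = None,
                      method: str = "mean") -> float:
    """Pearson r between two tracks on a common binning.

    With ``regions``, either correlate per-region mean densities
    (method='mean', the default) or the concatenated region-restricted bins
    (method='bins').  Zero variance on either side yields NaN.
    """
    if regions is None:
        x = np.concatenate([a[c] for c in sorted(a)])
        y = np.concatenate([b[c] for c in sorted(b)])
    elif method == "mean":
        if bin_size is None:
            raise ParameterError("bin_size required with regions")
        x = region_mean_density(a, bin_size, regions)
        y = region_mean_density(b, bin_size, regions)
    elif method == "bins":
        if bin_size is None:
            raise ParameterError("bin_size required with regions")
        xs, ys = [], []
        for chrom, start, end in regions:
            lo, hi = start // bin_size, -(-end // bin_size)
            xs.append(a[chrom][lo:hi])
            ys.append(b[chrom][lo:hi])
        x, y = np.concatenate(xs), np.concatenate(ys)
    else:
        raise ParameterError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("correlation undefined: zero variance")
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def write_bedgraph(arrays: dict[str, np.ndarray], bin_size: int, path) -> None:
    """4-column bedGraph (0-based half-open), merging equal adjacent bins."""
    with open(path, "w") as fh:
        for chrom in arrays:
            arr = arrays[chrom]
            i = 0
            while i < len(arr):
                j = i
                while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0.0:
                    fh.write(f"{chrom}\t{i * bin_size}\t{(j + 1) * bin_size}\t"
                             f"{arr[i]:.6g}\n")
                i = j + 1
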