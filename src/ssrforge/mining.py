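"""Microsatellite (SSR) mining: maximal tandem-run detection over chunked DNA.

An SSR locus here is a *maximal whole-copy tandem run* of a *primitive* motif
(a word that is not itself a repetition of a shorter word): the run cannot be
extended by one further unit, or slid by a partial-unit base, on either side.
Attributing every run to its minimal period exactly once is what keeps the
locus table free of redundant overlapping calls such as reporting an (AT)x6
tract a second time as (ATAT)x3.

Detection is per period ``k``: positions where ``seq[i] == seq[i+k]`` (both
unambiguous A/C/G/T, case-folded) form a boolean match array; each maximal
stretch of matches of length ``m`` delimits a repeat region of length
``m + k`` whose whole-copy run has ``(m + k) // k`` copies.  This is O(n) per
period via numpy, so genome-scale input is handled chunk by chunk with the
coordinates lifted back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .sequence_io import (
    DEFAULT_CHUNK_SIZE,
    DEFAULT_OVERLAP,
    Chunk,
    PathLike,
    SequenceRecord,
    chunk_sequence,
)

#: Inferred default: dimers through hexamers, at least 5 tandem copies each.
#: Monomer mining is off by default; enable with e.g. ``{1: 12}``.
DEFAULT_MIN_REPEATS: Dict[int, int] = {2: 5, 3: 5, 4: 5, 5: 5, 6: 5}

_BASES = "ACGT"


class MiningError(ValueError):
    """Invalid mining configuration or inconsistent locus input."""


@dataclass(frozen=True)
class MiningConfig:
    """Parameters controlling SSR detection.

    ``min_repeats`` maps motif unit length (bp) to the minimum tandem copy
    number required to report a run; unit lengths absent from the map are not
    mined.  ``containment_filter`` drops any locus whose interval lies within
    another reported locus (keeping the longer; on equal span, the shorter
    period).
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    chunk_size: int = DEFAULT_CHUNK_SIZE
    overlap: int = DEFAULT_OVERLAP
    containment_filter: bool = True

    @property
    def min_unit(self) -> int:
        return min(self.min_repeats)

    @property
    def max_unit(self) -> int:
        return max(self.min_repeats)

    def __post_init__(self) -> None:
        if not self.min_repeats:
            raise MiningError("min_repeats must not be empty")
        for unit, reps in self.min_repeats.items():
            if unit < 1:
                raise MiningError(f"unit length {unit} < 1")
            if reps < 2:
                raise MiningError(f"min_repeats[{unit}] = {reps}; must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """One mined tandem repeat, 1-based inclusive coordinates.

    ``motif`` is the unit exactly as it appears at ``start`` (no canonical
    rotation), so ``end - start + 1 == repetitions * len(motif)``.
    """

    seq_id: str
    seq_len: int
    start: int
    end: int
    repetitions: int
    motif: str

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.span != self.repetitions * len(self.motif):
            raise MiningError(
                f"inconsistent locus {self.seq_id}:{self.start}-{self.end} "
                f"({self.repetitions} x {self.motif})"
            )


@dataclass(frozen=True)
class MiningSummary:
    n_sequences: int
    total_length: int
    n_loci: int


def is_primitive(motif: str) -> bool:
    """True if the word is not an integer repetition of a shorter word."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def build_motif_library(min_unit: int, max_unit: int) -> List[str]:
    """All primitive motifs over ACGT for each unit length in range.

    Ordered by length ascending then lexicographically.  E.g. length 2 has
    12 motifs (16 dinucleotides minus the 4 homopolymer pairs).
    """
    if min_unit < 1:
        raise MiningError("min_unit must be >= 1")
    if max_unit < min_unit:
        raise MiningError("max_unit must be >= min_unit")
    library: List[str] = []
    for k in range(min_unit, max_unit + 1):
        for letters in product(_BASES, repeat=k):
            word = "".join(letters)
            if is_primitive(word):
                library.append(word)
    return library


# -- core scanner -----------------------------------------------------------

_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True
_UPPER = np.arange(256, dtype=np.uint8)
for _b in range(ord("a"), ord("z") + 1):
    _UPPER[_b] = _b - 32


def _encode(sequence: str) -> np.ndarray:
    """Uppercased byte array; non-ACGT bytes never participate in matches."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _UPPER[arr]


def find_ssrs(sequence: str, config: MiningConfig) -> List[SSRLocus]:
    """Find all maximal tandem runs in one sequence (local coordinates).

    Returns loci sorted by (start, unit length).  ``seq_id`` is left empty;
    callers attach identity and lift coordinates.
    """
    n = len(sequence)
    loci: List[SSRLocus] = []
    if n == 0:
        return loci
    arr = _encode(sequence)
    valid = _VALID[arr]
    upper = sequence.upper()
    for k, min_rep in sorted(config.min_repeats.items()):
        if n < k * min_rep:
            continue
        match = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        if not match.any():
            continue
        # maximal stretches of True in `match`
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]  # [start, stop) in match idx
        min_m = (min_rep - 1) * k
        keep = (stops - starts) >= min_m
        for i, m in zip(starts[keep], (stops - starts)[keep]):
            region = int(m) + k
            copies = region // k
            if copies < min_rep:
                continue
            motif = upper[i : i + k]
            if not is_primitive(motif):
                continue
            loci.append(
                SSRLocus(
                    seq_id="",
                    seq_len=n,
                    start=int(i) + 1,
                    end=int(i) + copies * k,
                    repetitions=int(copies),
                    motif=motif,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit))
    if config.containment_filter:
        loci = filter_contained(loci)
    return loci


def filter_contained(loci: Sequence[SSRLocus]) -> List[SSRLocus]:
    """Drop loci whose interval is contained in another locus's interval.

    The longer locus wins; on an exact interval tie the shorter period is
    kept (the more parsimonious description of the same stretch of DNA).
    """
    out: List[SSRLocus] = []
    by_seq: Dict[str, List[SSRLocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    for seq_id in by_seq:
        group = sorted(by_seq[seq_id], key=lambda l: (l.start, -l.span, l.unit))
        max_end = -1
        for locus in group:
            if locus.end <= max_end:
                continue  # contained in an earlier (longer or tied) locus
            max_end = locus.end
            out.append(locus)
    out.sort(key=lambda l: (l.seq_id, l.start, l.unit))
    return out


def _maximal_run(upper: str, pos: int, k: int) -> Tuple[int, int]:
    """Re-derive the maximal whole-copy run of period ``k`` around ``pos``.

    ``pos`` is a 0-based position known to lie in a period-``k`` repeat
    region.  Returns (0-based start, copies) of the leftmost-anchored
    whole-copy run, matching the scanner's convention.
    """
    n = len(upper)

    def ok(i: int) -> bool:
        a, b = upper[i], upper[i + k]
        return a == b and a in _BASES

    left = min(pos, n - k - 1)
    while left > 0 and ok(left - 1):
        left -= 1
    right = left  # first index where match fails
    while right + k < n and ok(right):
        right += 1
    region = right - left + k
    return left, region // k


def merge_chunk_loci(
    lifted: Sequence[SSRLocus],
    records: Mapping[str, SequenceRecord],
) -> List[SSRLocus]:
    """Combine per-chunk loci (already in parent coordinates) per sequence.

    Duplicate calls from overlapping chunks collapse to one.  Runs truncated
    at a chunk boundary — same minimal period, rotation-equivalent motifs,
    intervals overlapping or abutting in phase — are re-extended against the
    parent sequence so the merged locus is exactly what unchunked mining
    would report.  Output is sorted by (seq_id, start).
    """
    for locus in lifted:
        rec = records.get(locus.seq_id)
        if rec is None:
            raise MiningError(f"locus references unknown sequence {locus.seq_id!r}")
        if locus.seq_len != rec.length:
            raise MiningError(
                f"conflicting length for {locus.seq_id}: "
                f"{locus.seq_len} vs {rec.length}"
            )
    merged: Dict[Tuple[str, int, int, str], SSRLocus] = {}
    upper_cache: Dict[str, str] = {}
    for locus in sorted(lifted, key=lambda l: (l.seq_id, l.start, l.unit)):
        upper = upper_cache.get(locus.seq_id)
        if upper is None:
            upper = records[locus.seq_id].sequence.upper()
            upper_cache[locus.seq_id] = upper
        k = locus.unit
        start0, copies = _maximal_run(upper, locus.start - 1, k)
        motif = upper[start0 : start0 + k]
        if not is_primitive(motif):
            continue  # merged run collapses to a smaller period, found there
        full = replace(
            locus,
            start=start0 + 1,
            end=start0 + copies * k,
            repetitions=copies,
            motif=motif,
        )
        merged[(full.seq_id, full.start, full.end, full.motif)] = full
    out = sorted(merged.values(), key=lambda l: (l.seq_id, l.start, l.unit))
    return out


def mine_genome(
    records: Sequence[SequenceRecord],
    config: Optional[MiningConfig] = None,
) -> Tuple[List[SSRLocus], MiningSummary]:
    """Mine all records: chunk, scan, lift back, merge, filter.

    Chunking is invisible in the result: any chunk size at least twice the
    longest run yields the same locus table as unchunked mining.
    """
    config = config or MiningConfig()
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise MiningError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    rec_map = {rec.id: rec for rec in records}
    # Chunks are scanned at a floor of 2 copies: a run longer than the
    # overlap can be split so that neither chunk holds the full threshold
    # count, but each piece with >=2 copies re-extends on the parent to the
    # full run, after which the real thresholds apply.
    scan_cfg = replace(
        config,
        min_repeats={k: 2 for k in config.min_repeats},
        containment_filter=False,
    )
    all_loci: List[SSRLocus] = []
    for rec in records:
        lifted: List[SSRLocus] = []
        for chunk in chunk_sequence(rec, config.chunk_size, config.overlap):
            for locus in find_ssrs(chunk.sequence, scan_cfg):
                lifted.append(
                    replace(
                        locus,
                        seq_id=rec.id,
                        seq_len=rec.length,
                        start=locus.start + chunk.offset,
                        end=locus.end + chunk.offset,
                    )
                )
        merged = merge_chunk_loci(lifted, rec_map)
        merged = [
            l for l in merged if l.repetitions >= config.min_repeats[l.unit]
        ]
        if config.containment_filter:
            merged = filter_contained(merged)
        all_loci.extend(merged)
    summary = MiningSummary(
        n_sequences=len(records),
        total_length=sum(rec.length for rec in records),
        n_loci=len(all_loci),
    )
    return all_loci, summary


# -- .ssr / .sat1 files -----------------------------------------------------

SSR_HEADER = ["Name", "Seq_Len", "StartPos", "EndPos", "Repetitions", "Motif"]


def write_ssr(loci: Iterable[SSRLocus], path: PathLike) -> None:
    """Write the tab-separated locus table (Name carries a leading '>')."""
    with open(path, "w") as handle:
        handle.write("\t".join(SSR_HEADER) + "\n")
        for locus in loci:
            handle.write(
                f">{locus.seq_id}\t{locus.seq_len}\t{locus.start}\t"
                f"{locus.end}\t{locus.repetitions}\t{locus.motif}\n"
            )


def read_ssr(path: PathLike) -> List[SSRLocus]:
    loci: List[SSRLocus] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\r\n").split("\t")
        if header != SSR_HEADER:
            raise MiningError(f"{path}: unexpected .ssr header {header!r}")
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise MiningError(f"{path}:{line_no}: expected 6 columns")
            name, seq_len, start, end, reps, motif = fields
            loci.append(
                SSRLocus(
                    seq_id=name.lstrip(">"),
                    seq_len=int(seq_len),
                    start=int(start),
                    end=int(end),
                    repetitions=int(reps),
                    motif=motif,
                )
            )
    return loci


def write_sat1(summary: MiningSummary, path: PathLike) -> None:
    """Input-summary file: sequence count, total length, loci found."""
    with open(path, "w") as handle:
        handle.write(f"Total_sequences\t{summary.n_sequences}\n")
        handle.write(f"Total_length_bp\t{summary.total_length}\n")
        handle.write(f"Total_SSR_loci\t{summary.n_loci}\n")


def write_highlighted_fasta(
    records: Sequence[SequenceRecord],
    loci: Sequence[SSRLocus],
    path: PathLike,
    width: int = 70,
) -> None:
    """Write FASTA with SSR tracts uppercase and all other bases lowercase."""
    by_seq: Dict[str, List[SSRLocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    with open(path, "w") as handle:
        for rec in records:
            chars = list(rec.sequence.lower())
            for locus in by_seq.get(rec.id, []):
                for i in range(locus.start - 1, locus.end):
                    chars[i] = chars[i].upper()
            handle.write(f">{rec.id}\n")
            seq = "".join(chars)
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def parse_min_repeats(spec: str) -> Dict[int, int]:
    """Parse a ``unit=min`` spec such as ``"2=5,3=5,4=5"`` (``:`` also ok)."""
    result: Dict[int, int] = {}
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        sep = "=" if "=" in part else ":"
        try:
            unit, reps = part.split(sep)
            result[int(unit)] = int(reps)
        except ValueError as exc:
            raise MiningError(f"cannot parse min-repeats entry {part!r}") from exc
    if not result:
        raise MiningError(f"empty min-repeats spec {spec!r}")
    return result
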