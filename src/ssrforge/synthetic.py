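"""Synthetic genomes with planted microsatellites and known truth tables.

The generator emulates the one thing the toolkit needs from real data: long
stretches of repeat-free background interrupted by tandem repeat tracts at
known coordinates.  Background bases are i.i.d. at a chosen GC content;
accidental tandem runs are broken by targeted point substitutions, and the
bases bordering each planted tract are forced off-phase so that a planted
(motif, copies) tract is exactly the maximal run the miner must report.
Variant genomes with whole-unit insertions or deletions inside tracts model
allele-length polymorphism between related genotypes.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .mining import MiningConfig, SSRLocus, find_ssrs, is_primitive
from .sequence_io import PathLike, SequenceRecord

_BASES = "ACGT"

#: Cleaning thresholds: stricter than the default mining preset so the
#: background stays comfortably below any reportable run.
_CLEAN_MIN_REPEATS = {1: 6, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}


class FixtureError(ValueError):
    """Infeasible planting specification."""


@dataclass(frozen=True)
class Plant:
    """One tract to embed: ``start`` is 1-based, or None for random placement."""

    motif: str
    copies: int
    seq_index: int = 0
    start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.motif or any(c not in _BASES for c in self.motif.upper()):
            raise FixtureError(f"motif must be non-empty ACGT, got {self.motif!r}")
        if not is_primitive(self.motif.upper()):
            raise FixtureError(f"motif {self.motif!r} is not primitive")
        if self.copies < 2:
            raise FixtureError("copies must be >= 2")

    @property
    def span(self) -> int:
        return self.copies * len(self.motif)


@dataclass(frozen=True)
class PlantSpec:
    """Genome blueprint: sequence lengths, GC content, tracts, seed."""

    seq_lengths: Sequence[int]
    plants: Sequence[Plant]
    gc: float = 0.42
    seed: int = 0
    id_prefix: str = "chr"

    def __post_init__(self) -> None:
        if not self.seq_lengths:
            raise FixtureError("need at least one sequence length")
        if not 0.0 < self.gc < 1.0:
            raise FixtureError("gc must be in (0, 1)")
        for plant in self.plants:
            if plant.seq_index >= len(self.seq_lengths):
                raise FixtureError(f"plant references sequence {plant.seq_index}")
            if plant.start is not None:
                end = plant.start + plant.span - 1
                if plant.start < 3 or end > self.seq_lengths[plant.seq_index] - 2:
                    raise FixtureError(
                        f"tract {plant.motif}x{plant.copies} at {plant.start} "
                        "does not fit with a 2 bp margin"
                    )


@dataclass(frozen=True)
class PlantedLocus:
    """Truth-table row for one planted tract (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    motif: str
    copies: int
    size_delta: int = 0  # bp added/removed relative to the base genome

    def as_ssr_locus(self, seq_len: int) -> SSRLocus:
        return SSRLocus(
            seq_id=self.seq_id,
            seq_len=seq_len,
            start=self.start,
            end=self.end,
            repetitions=self.copies,
            motif=self.motif,
        )


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _break_runs(arr: np.ndarray, rng: np.random.Generator, max_iter: int = 60) -> None:
    """Point-substitute the middle of accidental tandem runs until clean."""
    cfg = MiningConfig(min_repeats=dict(_CLEAN_MIN_REPEATS), containment_filter=False)
    for _ in range(max_iter):
        seq = arr.tobytes().decode("ascii")
        runs = find_ssrs(seq, cfg)
        if not runs:
            return
        for run in runs:
            mid = (run.start + run.end) // 2 - 1
            old = arr[mid]
            choices = [b for b in b"ACGT" if b != old]
            arr[mid] = choices[int(rng.integers(len(choices)))]
    raise FixtureError("could not scrub accidental repeats from background")


def _fix_boundary(arr: np.ndarray, idx: int, forbidden: Iterable[int], rng: np.random.Generator) -> None:
    forbidden = set(forbidden)
    if idx < 0 or idx >= len(arr) or arr[idx] not in forbidden:
        return
    choices = [b for b in b"ACGT" if b not in forbidden]
    arr[idx] = choices[int(rng.integers(len(choices)))]


def _place_random(
    rng: np.random.Generator,
    length: int,
    span: int,
    taken: List[Tuple[int, int]],
    spacer: int = 2,
) -> int:
    """A random 1-based start keeping >=spacer bp from other tracts."""
    for _ in range(2000):
        start = int(rng.integers(3, length - span - 1))
        end = start + span - 1
        if all(end < s - spacer or start > e + spacer for s, e in taken):
            return start
    raise FixtureError("could not place tract without overlap; spec too dense")


def generate_genome(
    spec: PlantSpec,
    verify_config: Optional[MiningConfig] = None,
) -> Tuple[List[SequenceRecord], List[PlantedLocus]]:
    """Build FASTA records and the matching truth table.

    If ``verify_config`` is given, the result is checked: mining each record
    with that configuration must recover exactly the planted loci, otherwise
    stray background runs are repaired (never the tracts themselves).
    """
    rng = np.random.default_rng(spec.seed)
    arrays: List[np.ndarray] = []
    for length in spec.seq_lengths:
        arr = _random_background(rng, length, spec.gc)
        _break_runs(arr, rng)
        arrays.append(arr)

    taken: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(len(arrays))}
    truth: List[PlantedLocus] = []
    for plant in spec.plants:
        arr = arrays[plant.seq_index]
        span = plant.span
        if plant.start is not None:
            start = plant.start
            end = start + span - 1
            if any(
                not (end < s - 2 or start > e + 2) for s, e in taken[plant.seq_index]
            ):
                raise FixtureError(f"tract at {start} overlaps a previous tract")
        else:
            start = _place_random(rng, len(arr), span, taken[plant.seq_index])
            end = start + span - 1
        motif = plant.motif.upper()
        tract = (motif * plant.copies).encode("ascii")
        arr[start - 1 : end] = np.frombuffer(tract, dtype=np.uint8)
        # block same-period extension/slippage across the tract boundary
        _fix_boundary(arr, start - 2, [ord(motif[-1])], rng)
        _fix_boundary(arr, end, [ord(motif[0])], rng)
        taken[plant.seq_index].append((start, end))
        truth.append(
            PlantedLocus(
                seq_id=f"{spec.id_prefix}{plant.seq_index + 1}",
                start=start,
                end=end,
                motif=motif,
                copies=plant.copies,
            )
        )

    records = [
        SequenceRecord(id=f"{spec.id_prefix}{i + 1}", sequence=arr.tobytes().decode("ascii"))
        for i, arr in enumerate(arrays)
    ]
    truth.sort(key=lambda t: (t.seq_id, t.start))
    if verify_config is not None:
        records = _repair_against_truth(records, truth, verify_config, rng)
    return records, truth


def _repair_against_truth(
    records: List[SequenceRecord],
    truth: Sequence[PlantedLocus],
    config: MiningConfig,
    rng: np.random.Generator,
    max_iter: int = 40,
) -> List[SequenceRecord]:
    expected = {
        (t.seq_id, t.start, t.end, t.motif) for t in truth
    }
    tract_spans: Dict[str, List[Tuple[int, int]]] = {}
    for t in truth:
        tract_spans.setdefault(t.seq_id, []).append((t.start, t.end))
    for _ in range(max_iter):
        extras: List[SSRLocus] = []
        missing = set(expected)
        for rec in records:
            for locus in find_ssrs(rec.sequence, config):
                key = (rec.id, locus.start, locus.end, locus.motif)
                if key in expected:
                    missing.discard(key)
                else:
                    extras.append(replace(locus, seq_id=rec.id))
        if missing:
            raise FixtureError(f"planted loci not recovered: {sorted(missing)[:3]}")
        if not extras:
            return records
        arrays = {rec.id: bytearray(rec.sequence.encode("ascii")) for rec in records}
        for extra in extras:
            spans = tract_spans.get(extra.seq_id, [])
            # mutate a base of the stray run lying outside every real tract
            for pos in range((extra.start + extra.end) // 2, extra.end + 1):
                if all(not (s <= pos <= e) for s, e in spans):
                    old = arrays[extra.seq_id][pos - 1]
                    choices = [b for b in b"ACGT" if b != old]
                    arrays[extra.seq_id][pos - 1] = choices[int(rng.integers(3))]
                    break
        records = [
            SequenceRecord(id=rec.id, sequence=arrays[rec.id].decode("ascii"))
            for rec in records
        ]
    raise FixtureError("could not reconcile genome with truth table")


def mutate_alleles(
    records: Sequence[SequenceRecord],
    truth: Sequence[PlantedLocus],
    deltas: Mapping[int, int],
    seed: int = 0,
    id_suffix: str = "_v",
) -> Tuple[List[SequenceRecord], List[PlantedLocus]]:
    """Variant genome with whole-unit copy-number changes inside tracts.

    ``deltas`` maps truth-table row index to a copy-number delta (can be
    negative; reaching 0 deletes the tract).  Flanking sequence is
    byte-identical to the source; only tract contents and downstream
    coordinates change.  Returns the variant records (ids suffixed) and an
    updated truth table carrying each tract's size delta in bp.
    """
    for idx, delta in deltas.items():
        if not 0 <= idx < len(truth):
            raise FixtureError(f"no truth row {idx}")
        if truth[idx].copies + delta < 0:
            raise FixtureError(
                f"delta {delta} exceeds tract of {truth[idx].copies} copies"
            )
    by_seq: Dict[str, List[Tuple[int, PlantedLocus]]] = {}
    for i, t in enumerate(truth):
        by_seq.setdefault(t.seq_id, []).append((i, t))
    new_records: List[SequenceRecord] = []
    new_truth: List[PlantedLocus] = []
    for rec in records:
        rows = sorted(by_seq.get(rec.id, []), key=lambda it: it[1].start)
        pieces: List[str] = []
        cursor = 0  # 0-based position in source
        shift = 0
        for i, t in rows:
            delta = deltas.get(i, 0)
            pieces.append(rec.sequence[cursor : t.start - 1])
            new_copies = t.copies + delta
            pieces.append(t.motif * new_copies)
            cursor = t.end
            new_start = t.start + shift
            size_delta = delta * len(t.motif)
            shift += size_delta
            if new_copies > 0:
                new_truth.append(
                    PlantedLocus(
                        seq_id=rec.id + id_suffix,
                        start=new_start,
                        end=new_start + new_copies * len(t.motif) - 1,
                        motif=t.motif,
                        copies=new_copies,
                        size_delta=size_delta,
                    )
                )
        pieces.append(rec.sequence[cursor:])
        new_records.append(
            SequenceRecord(id=rec.id + id_suffix, sequence="".join(pieces))
        )
    new_truth.sort(key=lambda t: (t.seq_id, t.start))
    return new_records, new_truth


def write_truth(truth: Iterable[PlantedLocus], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("#Seq_ID\tStartPos\tEndPos\tMotif\tCopies\tSize_delta\n")
        for t in truth:
            handle.write(
                f"{t.seq_id}\t{t.start}\t{t.end}\t{t.motif}\t{t.copies}\t{t.size_delta}\n"
            )


def read_truth(path: PathLike) -> List[PlantedLocus]:
    out: List[PlantedLocus] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            sid, start, end, motif, copies, delta = line.split("\t")
            out.append(
                PlantedLocus(sid, int(start), int(end), motif, int(copies), int(delta))
            )
    return out


def random_plants(
    n: int,
    rng: np.random.Generator,
    n_seqs: int = 1,
    units: Sequence[int] = (2, 3, 4),
    copies_range: Tuple[int, int] = (5, 12),
) -> List[Plant]:
    """Convenience: n random primitive-motif tracts spread over sequences."""
    from .mining import build_motif_library

    plants: List[Plant] = []
    for _ in range(n):
        k = int(rng.choice(list(units)))
        library = build_motif_library(k, k)
        motif = library[int(rng.integers(len(library)))]
        copies = int(rng.integers(copies_range[0], copies_range[1] + 1))
        plants.append(Plant(motif=motif, copies=copies, seq_index=int(rng.integers(n_seqs))))
    return plants
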