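"""SSR marker design: primer pairs from flanking windows, deduplicated.

Rather than handing a whole chromosome to the primer engine, a short window
(default 400 bp each side) is extracted around every locus, so design cost
scales with the number of loci, not genome length.  One primer sits wholly
in each flank — never inside the repeat tract — and the top-ranked feasible
pair is reported with coordinates lifted back to the source sequence.

The built-in designer enumerates candidate oligos by 3'-end position and
length, applies hard length / GC / melting-temperature / homopolymer
constraints, and ranks pairs by closeness to the target Tm plus the Tm
difference between mates.  Melting temperatures use the nearest-neighbour
model (Biopython ``Tm_NN``, SantaLucia 1997 parameters at the default
50 mM Na+ / 25 nM oligo conditions), pinned here for reproducibility.

Identical (left, right) pairs — e.g. from duplicated regions — collapse to
one marker; ids are assigned MK1, MK2, ... in order of first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio.Seq import reverse_complement
from Bio.SeqUtils import MeltingTemp as mt

from .mining import SSRLocus
from .sequence_io import PathLike, SequenceRecord, extract_flank


class MarkerError(ValueError):
    """Invalid marker-design input."""


@dataclass(frozen=True)
class PrimerParams:
    """Design constraints.

    Units: bp for lengths and product sizes, degrees C for temperatures,
    percent for GC bounds.
    """

    flank: int = 400
    product_min: int = 100
    product_max: int = 400
    tm_opt: float = 60.0
    tm_min: float = 57.0
    tm_max: float = 63.0
    primer_min: int = 18
    primer_max: int = 27
    gc_min: float = 20.0
    gc_max: float = 80.0
    max_poly_x: int = 4  # longest allowed single-base run in a primer
    max_candidates_per_side: int = 40

    def __post_init__(self) -> None:
        if self.product_min < 2 * self.primer_min:
            raise MarkerError(
                "product_min must be at least the two minimum primer lengths"
            )
        if not (self.primer_min <= self.primer_max):
            raise MarkerError("invalid primer length range")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; ``right`` is the reverse-strand primer as ordered.

    ``left_start``/``right_end`` are 1-based inclusive parent coordinates of
    the amplified product's ends, so
    ``product_size == right_end - left_start + 1``.
    """

    left: str
    right: str
    product_size: int
    left_start: int
    right_end: int
    tm_left: float
    tm_right: float


@dataclass(frozen=True)
class DesignedPair:
    """A primer pair together with the locus it was designed for."""

    pair: PrimerPair
    locus: SSRLocus


@dataclass
class Marker:
    marker_id: str
    pair: PrimerPair
    product_size: int
    motif: str
    source_loci: List[Tuple[str, int, int]]
    all_sizes: List[int] = field(default_factory=list)


@dataclass(frozen=True)
class DesignFailure:
    locus: SSRLocus
    reason: str


def primer_tm(seq: str) -> float:
    """Nearest-neighbour melting temperature under PCR-buffer conditions.

    50 mM monovalent salt, 1.5 mM Mg2+, 50 nM oligo, Owczarzy (2008) salt
    correction — the conventional conditions under which a typical 20-mer
    marker primer sits near 60 degrees C.
    """
    return float(mt.Tm_NN(seq, Na=50, Mg=1.5, dnac1=50, dnac2=0, saltcorr=7))


def _gc_percent(seq: str) -> float:
    seq = seq.upper()
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def _has_long_run(seq: str, max_run: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


@dataclass(frozen=True)
class _Candidate:
    start: int  # 0-based in window
    end: int  # 0-based inclusive in window
    seq: str  # primer 5'->3'
    tm: float
    penalty: float


def _passes(seq: str, params: PrimerParams) -> Optional[float]:
    """Hard constraints; returns Tm if the oligo is acceptable."""
    up = seq.upper()
    if any(c not in "ACGT" for c in up):
        return None
    if not (params.gc_min <= _gc_percent(up) <= params.gc_max):
        return None
    if _has_long_run(up, params.max_poly_x):
        return None
    tm = primer_tm(up)
    if not (params.tm_min <= tm <= params.tm_max):
        return None
    return tm


def _left_candidates(
    window: str, locus_start: int, locus_end: int, params: PrimerParams
) -> List[_Candidate]:
    """Forward-strand oligos ending strictly before the tract."""
    out: List[_Candidate] = []
    lo_start = max(0, locus_end + params.primer_min - params.product_max + 1)
    for end in range(locus_start - 1, params.primer_min - 2, -1):
        for length in range(params.primer_min, params.primer_max + 1):
            start = end - length + 1
            if start < lo_start:
                break
            seq = window[start : end + 1]
            tm = _passes(seq, params)
            if tm is not None:
                out.append(_Candidate(start, end, seq.upper(), tm, abs(tm - params.tm_opt)))
    out.sort(key=lambda c: (c.penalty, -c.end, len(c.seq)))
    return out[: params.max_candidates_per_side]


def _right_candidates(
    window: str, locus_start: int, locus_end: int, params: PrimerParams
) -> List[_Candidate]:
    """Reverse-strand oligos whose binding site starts after the tract."""
    out: List[_Candidate] = []
    n = len(window)
    hi_end = min(n - 1, locus_start - params.primer_min + params.product_max - 1)
    for start in range(locus_end + 1, n - params.primer_min + 1):
        for length in range(params.primer_min, params.primer_max + 1):
            end = start + length - 1
            if end > hi_end:
                break
            site = window[start : end + 1]
            seq = reverse_complement(site.upper())
            tm = _passes(seq, params)
            if tm is not None:
                out.append(_Candidate(start, end, seq, tm, abs(tm - params.tm_opt)))
    out.sort(key=lambda c: (c.penalty, c.start, len(c.seq)))
    return out[: params.max_candidates_per_side]


def design_primer_pair(
    window: str,
    locus_start: int,
    locus_end: int,
    params: Optional[PrimerParams] = None,
    window_parent_start: int = 1,
) -> Tuple[Optional[PrimerPair], Optional[str]]:
    """Design the best primer pair bracketing a tract within a window.

    ``locus_start``/``locus_end`` are 0-based inclusive indices of the
    repeat tract *within the window*; ``window_parent_start`` is the 1-based
    parent position of the window's first base, used to lift the reported
    coordinates.  Returns ``(pair, None)`` on success or ``(None, reason)``.
    """
    params = params or PrimerParams()
    if not (0 <= locus_start <= locus_end < len(window)):
        raise MarkerError("locus interval outside window")
    if len(window) < params.product_min:
        return None, "window_too_short"
    if locus_start < params.primer_min:
        return None, "no_left_flank"
    if len(window) - locus_end - 1 < params.primer_min:
        return None, "no_right_flank"
    lefts = _left_candidates(window, locus_start, locus_end, params)
    if not lefts:
        return None, "no_left_candidates"
    rights = _right_candidates(window, locus_start, locus_end, params)
    if not rights:
        return None, "no_right_candidates"
    best: Optional[Tuple[float, int, int, _Candidate, _Candidate]] = None
    for l in lefts:
        for r in rights:
            product = r.end - l.start + 1
            if not (params.product_min <= product <= params.product_max):
                continue
            score = l.penalty + r.penalty + abs(l.tm - r.tm)
            key = (score, product, l.start)
            if best is None or key < (best[0], best[1], best[2]):
                best = (score, product, l.start, l, r)
    if best is None:
        return None, "no_pair_in_size_range"
    _, product, _, l, r = best
    pair = PrimerPair(
        left=l.seq,
        right=r.seq,
        product_size=product,
        left_start=window_parent_start + l.start,
        right_end=window_parent_start + r.end,
        tm_left=round(l.tm, 2),
        tm_right=round(r.tm, 2),
    )
    return pair, None


def design_all(
    loci: Sequence[SSRLocus],
    records: Sequence[SequenceRecord],
    params: Optional[PrimerParams] = None,
) -> Tuple[List[DesignedPair], List[DesignFailure]]:
    """One design attempt per locus; failures are logged, never fatal."""
    params = params or PrimerParams()
    rec_map = {rec.id: rec for rec in records}
    designed: List[DesignedPair] = []
    failures: List[DesignFailure] = []
    for locus in loci:
        rec = rec_map.get(locus.seq_id)
        if rec is None:
            failures.append(DesignFailure(locus, "unknown_sequence"))
            continue
        window, win_start = extract_flank(rec, locus.start, locus.end, params.flank)
        pair, reason = design_primer_pair(
            window,
            locus.start - win_start,
            locus.end - win_start,
            params,
            window_parent_start=win_start,
        )
        if pair is None:
            failures.append(DesignFailure(locus, reason or "unknown"))
        else:
            designed.append(DesignedPair(pair=pair, locus=locus))
    return designed, failures


def deduplicate_markers(designed: Sequence[DesignedPair]) -> List[Marker]:
    """Collapse 100%-identical (left, right) pairs into unique markers."""
    markers: Dict[Tuple[str, str], Marker] = {}
    for d in designed:
        key = (d.pair.left, d.pair.right)
        if key not in markers:
            markers[key] = Marker(
                marker_id=f"MK{len(markers) + 1}",
                pair=d.pair,
                product_size=d.pair.product_size,
                motif=d.locus.motif,
                source_loci=[],
            )
        marker = markers[key]
        marker.source_loci.append((d.locus.seq_id, d.locus.start, d.locus.end))
        if d.pair.product_size not in marker.all_sizes:
            marker.all_sizes.append(d.pair.product_size)
    return list(markers.values())


# -- .sts / .mk files -------------------------------------------------------

STS_HEADER = "#Marker_ID\tLeft_primer_sequence\tRight_primer_sequence\tProduct_size"
MK_HEADER = STS_HEADER + "\tRepeated_motif\tSource_loci"


def write_sts(markers: Iterable[Marker], path: PathLike) -> None:
    """NCBI STS-style tab format: id, forward primer, reverse primer, size."""
    with open(path, "w") as handle:
        handle.write(STS_HEADER + "\n")
        for m in markers:
            handle.write(
                f">{m.marker_id}\t{m.pair.left}\t{m.pair.right}\t{m.product_size}\n"
            )


def write_mk(markers: Iterable[Marker], path: PathLike) -> None:
    """Extended marker table adding the repeated motif and source loci."""
    with open(path, "w") as handle:
        handle.write(MK_HEADER + "\n")
        for m in markers:
            sources = ";".join(f"{s}:{a}-{b}" for s, a, b in m.source_loci)
            handle.write(
                f">{m.marker_id}\t{m.pair.left}\t{m.pair.right}\t"
                f"{m.product_size}\t{m.motif}\t{sources}\n"
            )


def read_sts(path: PathLike) -> List[Marker]:
    """Read an STS table (ours or pre-existing markers in the same dialect)."""
    markers: List[Marker] = []
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MarkerError(f"{path}:{line_no}: expected >=4 columns")
            marker_id, left, right, size = fields[:4]
            motif = fields[4] if len(fields) > 4 else ""
            sources: List[Tuple[str, int, int]] = []
            if len(fields) > 5 and fields[5]:
                for token in fields[5].split(";"):
                    seq_id, span = token.rsplit(":", 1)
                    a, b = span.split("-")
                    sources.append((seq_id, int(a), int(b)))
            size_i = int(size)
            markers.append(
                Marker(
                    marker_id=marker_id.lstrip(">"),
                    pair=PrimerPair(
                        left=left,
                        right=right,
                        product_size=size_i,
                        left_start=0,
                        right_end=0,
                        tm_left=0.0,
                        tm_right=0.0,
                    ),
                    product_size=size_i,
                    motif=motif,
                    source_loci=sources,
                    all_sizes=[size_i],
                )
            )
    return markers
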