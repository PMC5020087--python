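"""Electronic PCR: map STS markers onto sequences and score polymorphism.

A marker amplifies wherever its two primers bind convergently — the left
primer on one strand and the right primer's complement downstream on the
other — within configured product-size bounds, in either template
orientation.  Primer sites may tolerate internal mismatches, but the
3'-terminal bases must match exactly (extension cannot start from a
mismatched 3' end).  Predicted product sizes are the marker's alleles; a
marker is polymorphic when different targets yield different allele sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .markers import Marker
from .sequence_io import PathLike, SequenceRecord


class EpcrError(ValueError):
    """Invalid e-PCR configuration or input."""


@dataclass(frozen=True)
class EpcrParams:
    """Site-matching and product-size constraints.

    ``size_margin`` (bp around a marker's declared product size) is applied
    only when it is set; the absolute ``size_min``/``size_max`` bounds always
    apply and keep pathological genome-spanning pairings out.
    """

    max_mismatches: int = 0
    max_gaps: int = 0
    exact_3prime: int = 3
    size_min: int = 50
    size_max: int = 5000
    size_margin: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.max_mismatches, self.max_gaps, self.exact_3prime) < 0:
            raise EpcrError("e-PCR parameters must be non-negative")
        if self.max_gaps > 0:
            raise EpcrError("gapped primer matching is not supported")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based start of the binding site on the template
    strand: str  # '+' primer matches forward strand, '-' its complement
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    marker_id: str
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    size: int
    strand: str  # strand carrying the left primer
    mismatches_left: int = 0
    mismatches_right: int = 0


@dataclass(frozen=True)
class MappingSummary:
    allele_distribution: Dict[int, int]  # distinct allele count -> n markers
    n_sequences_with_marker: int
    n_markers_mapped: int
    total_amplicons: int
    mean_amplicons_per_mapped_marker: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _match_positions(template: np.ndarray, word: str, budget: int, exact_head: int = 0, exact_tail: int = 0) -> List[Tuple[int, int]]:
    """All start positions where ``word`` matches with <= budget mismatches.

    ``exact_head``/``exact_tail`` bases of the word must match exactly.
    Returns (position, mismatches) pairs.
    """
    m = len(word)
    n = len(template)
    if m > n:
        return []
    w = _encode(word)
    n_pos = n - m + 1
    mism = np.zeros(n_pos, dtype=np.int16)
    for j in range(m):
        mism += template[j : j + n_pos] != w[j]
    ok = mism <= budget
    if exact_head:
        head_ok = np.ones(n_pos, dtype=bool)
        for j in range(exact_head):
            head_ok &= template[j : j + n_pos] == w[j]
        ok &= head_ok
    if exact_tail:
        tail_ok = np.ones(n_pos, dtype=bool)
        for j in range(m - exact_tail, m):
            tail_ok &= template[j : j + n_pos] == w[j]
        ok &= tail_ok
    return [(int(p), int(mism[p])) for p in np.flatnonzero(ok)]


def find_primer_sites(
    sequence: str, primer: str, params: Optional[EpcrParams] = None
) -> List[PrimerSite]:
    """All binding sites of a primer on both strands of a template.

    A '+' site is a forward-strand match of the primer itself; a '-' site is
    a match of its reverse complement (the primer anneals to the forward
    strand and extends leftwards).  The primer's 3'-terminal bases are
    required to match exactly: the last bases of the word for '+' sites, the
    first bases of the reverse-complemented word for '-' sites.
    """
    params = params or EpcrParams()
    if len(primer) < params.exact_3prime:
        raise EpcrError("primer shorter than required exact 3'-end length")
    template = _encode(sequence)
    sites: List[PrimerSite] = []
    for pos, mism in _match_positions(
        template, primer, params.max_mismatches, exact_tail=params.exact_3prime
    ):
        sites.append(PrimerSite(pos, "+", mism))
    rc = reverse_complement(primer.upper())
    for pos, mism in _match_positions(
        template, rc, params.max_mismatches, exact_head=params.exact_3prime
    ):
        sites.append(PrimerSite(pos, "-", mism))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def _size_ok(size: int, declared: int, params: EpcrParams) -> bool:
    if not (params.size_min <= size <= params.size_max):
        return False
    if params.size_margin is not None and declared > 0:
        return abs(size - declared) <= params.size_margin
    return True


def epcr(
    markers: Sequence[Marker],
    records: Sequence[SequenceRecord],
    params: Optional[EpcrParams] = None,
) -> List[Amplicon]:
    """Predict all amplicons of the markers on the target sequences.

    Both template orientations are considered: the canonical pairing (left
    primer forward, right primer's complement downstream) and its mirror
    (right primer forward, left primer's complement downstream), which is
    the same product read from the other strand.  Duplicate coordinate
    pairs collapse.
    """
    params = params or EpcrParams()
    amplicons: Dict[Tuple[str, str, int, int], Amplicon] = {}
    for rec in records:
        template = _encode(rec.sequence)
        for marker in markers:
            left, right = marker.pair.left, marker.pair.right
            pairings = [
                # (upstream word, downstream word = rc of mate, strand label)
                (left, reverse_complement(right.upper()), "+", True),
                (right, reverse_complement(left.upper()), "-", False),
            ]
            for up_word, down_word, strand, left_is_up in pairings:
                ups = _match_positions(
                    template,
                    up_word,
                    params.max_mismatches,
                    exact_tail=params.exact_3prime,
                )
                if not ups:
                    continue
                downs = _match_positions(
                    template,
                    down_word,
                    params.max_mismatches,
                    exact_head=params.exact_3prime,
                )
                for p, mism_up in ups:
                    for q, mism_down in downs:
                        end = q + len(down_word) - 1
                        if q < p + len(up_word):
                            continue  # primers must converge, not overlap
                        size = end - p + 1
                        if not _size_ok(size, marker.product_size, params):
                            continue
                        key = (marker.marker_id, rec.id, p + 1, end + 1)
                        if key in amplicons:
                            continue
                        ml = mism_up if left_is_up else mism_down
                        mr = mism_down if left_is_up else mism_up
                        amplicons[key] = Amplicon(
                            marker_id=marker.marker_id,
                            seq_id=rec.id,
                            start=p + 1,
                            end=end + 1,
                            size=size,
                            strand=strand,
                            mismatches_left=ml,
                            mismatches_right=mr,
                        )
    out = list(amplicons.values())
    out.sort(key=lambda a: (a.seq_id, a.marker_id, a.start, a.end))
    return out


def score_polymorphism(
    amplicons: Sequence[Amplicon],
    markers: Sequence[Marker],
    records: Sequence[SequenceRecord],
) -> Tuple[pd.DataFrame, Dict[str, bool]]:
    """Allele-size matrix (markers x targets) and per-marker polymorphism.

    A cell holds the ascending product sizes joined with "+", or "NA" when
    the marker does not amplify on that target.  A marker is polymorphic
    when at least two distinct non-NA cell values occur across targets.
    """
    sizes: Dict[Tuple[str, str], List[int]] = {}
    for amp in amplicons:
        sizes.setdefault((amp.marker_id, amp.seq_id), []).append(amp.size)
    rows = []
    flags: Dict[str, bool] = {}
    for marker in markers:
        row = {"Marker_ID": marker.marker_id}
        cells = set()
        for rec in records:
            got = sizes.get((marker.marker_id, rec.id))
            if got:
                cell = "+".join(str(s) for s in sorted(got))
                cells.add(cell)
            else:
                cell = "NA"
            row[rec.id] = cell
        flags[marker.marker_id] = len(cells) >= 2
        row["Polymorphic"] = "yes" if flags[marker.marker_id] else "no"
        rows.append(row)
    columns = ["Marker_ID"] + [rec.id for rec in records] + ["Polymorphic"]
    return pd.DataFrame(rows, columns=columns), flags


def summarize_mapping(
    amplicons: Sequence[Amplicon],
    markers: Sequence[Marker],
    records: Sequence[SequenceRecord],
) -> MappingSummary:
    """The `.sat4` quantities; mean is 0 when nothing maps."""
    per_marker_sizes: Dict[str, set] = {m.marker_id: set() for m in markers}
    mapped_seqs = set()
    for amp in amplicons:
        per_marker_sizes.setdefault(amp.marker_id, set()).add(amp.size)
        mapped_seqs.add(amp.seq_id)
    dist: Dict[int, int] = {}
    for marker in markers:
        n_alleles = len(per_marker_sizes[marker.marker_id])
        dist[n_alleles] = dist.get(n_alleles, 0) + 1
    n_mapped = sum(1 for m in markers if per_marker_sizes[m.marker_id])
    total = len(amplicons)
    mean = total / n_mapped if n_mapped else 0.0
    return MappingSummary(
        allele_distribution=dict(sorted(dist.items())),
        n_sequences_with_marker=len(mapped_seqs),
        n_markers_mapped=n_mapped,
        total_amplicons=total,
        mean_amplicons_per_mapped_marker=mean,
    )


# -- report files -----------------------------------------------------------

AMP_HEADER = "#Marker_ID\tName\tStartPos\tEndPos\tStrand\tSize\tMism_left\tMism_right"


def write_amp(amplicons: Iterable[Amplicon], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write(AMP_HEADER + "\n")
        for a in amplicons:
            handle.write(
                f"{a.marker_id}\t{a.seq_id}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{a.size}\t{a.mismatches_left}\t{a.mismatches_right}\n"
            )


def read_amp(path: PathLike) -> List[Amplicon]:
    out: List[Amplicon] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            mk, sid, start, end, strand, size, ml, mr = line.split("\t")
            out.append(
                Amplicon(mk, sid, int(start), int(end), int(size), strand, int(ml), int(mr))
            )
    return out


def write_frg(matrix: pd.DataFrame, path: PathLike) -> None:
    """Allele matrix with NA cells, Table-style, tab separated."""
    matrix.to_csv(path, sep="\t", index=False)


def write_emap(
    amplicons: Sequence[Amplicon], records: Sequence[SequenceRecord], path: PathLike
) -> None:
    """Per-sequence list of mapped markers and their placements."""
    by_seq: Dict[str, List[Amplicon]] = {rec.id: [] for rec in records}
    for amp in amplicons:
        by_seq.setdefault(amp.seq_id, []).append(amp)
    with open(path, "w") as handle:
        for seq_id in by_seq:
            amps = sorted(by_seq[seq_id], key=lambda a: (a.start, a.marker_id))
            names = ";".join(f"{a.marker_id}:{a.start}-{a.end}" for a in amps)
            handle.write(f"{seq_id}\t{len(amps)}\t{names}\n")


def write_sat4(summary: MappingSummary, path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("# e-mapping summary\n")
        handle.write("Alleles_per_marker\tMarkers\n")
        for n_alleles, count in summary.allele_distribution.items():
            handle.write(f"{n_alleles}\t{count}\n")
        handle.write(f"Sequences_with_markers\t{summary.n_sequences_with_marker}\n")
        handle.write(f"Markers_mapped\t{summary.n_markers_mapped}\n")
        handle.write(f"Total_amplicons\t{summary.total_amplicons}\n")
        handle.write(
            "Mean_amplicons_per_mapped_marker\t"
            f"{summary.mean_amplicons_per_mapped_marker:.4g}\n"
        )
        if summary.n_markers_mapped == 0:
            handle.write("# note: no markers mapped\n")
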