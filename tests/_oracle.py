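"""Independent brute-force oracle for maximal tandem-run enumeration.

A deliberately different algorithm from the production scanner: for every
primitive motif of each period, greedy regex matching enumerates leftmost
whole-copy runs; rotated re-discoveries of the same run (overlap of at least
one unit at the same period) are dropped in favour of the leftmost; the
containment rule is applied by a quadratic all-pairs sweep.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Dict, List

from ssrforge.mining import SSRLocus, build_motif_library


@lru_cache(maxsize=None)
def _patterns(k: int, min_rep: int):
    return [
        (motif, re.compile(f"(?:{motif}){{{min_rep},}}"))
        for motif in build_motif_library(k, k)
    ]


def oracle_find_ssrs(
    sequence: str, min_repeats: Dict[int, int], containment_filter: bool = True
) -> List[SSRLocus]:
    up = sequence.upper()
    n = len(up)
    loci: List[SSRLocus] = []
    for k, min_rep in sorted(min_repeats.items()):
        candidates = []
        # prescreen: a run of >=2 copies implies the doubled motif occurs
        doubled = {up[i : i + 2 * k] for i in range(max(0, n - 2 * k + 1))}
        for motif, pattern in _patterns(k, min_rep):
            if motif * 2 not in doubled:
                continue
            for m in pattern.finditer(up):
                candidates.append((m.start(), m.end(), motif))
        candidates.sort()
        max_kept_end = -1
        for start, end, motif in candidates:
            if max_kept_end - start >= k:
                continue  # a rotation of a run already reported at this period
            copies = (end - start) // k
            loci.append(
                SSRLocus(
                    seq_id="",
                    seq_len=n,
                    start=start + 1,
                    end=start + copies * k,
                    repetitions=copies,
                    motif=motif,
                )
            )
            max_kept_end = max(max_kept_end, start + copies * k)
    if containment_filter:
        loci = _oracle_containment(loci)
    loci.sort(key=lambda l: (l.start, l.unit))
    return loci


def _oracle_containment(loci: List[SSRLocus]) -> List[SSRLocus]:
    kept = []
    for a in loci:
        dominated = False
        for b in loci:
            if a is b:
                continue
            if b.start <= a.start and b.end >= a.end:
                if b.span > a.span or (b.span == a.span and b.unit < a.unit):
                    dominated = True
                    break
        if not dominated:
            kept.append(a)
    return kept
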