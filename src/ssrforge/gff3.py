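"""Export SSR loci and markers as GFF3 tracks for genome browsers.

Loci become ``microsatellite`` features and marker placements become ``STS``
features (both Sequence Ontology terms), 1-based inclusive, matching the
``.ssr`` and ``.amp`` tables exactly so the browser shows the same intervals
the reports do.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
from urllib.parse import quote

from .epcr import Amplicon
from .markers import Marker
from .mining import SSRLocus
from .sequence_io import PathLike

SOURCE = "ssrforge"

# GFF3 reserves ; = & , and % in attribute values
_SAFE = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.:^*$@!+_?-|/() "


def _attr(pairs: Sequence[Tuple[str, str]]) -> str:
    return ";".join(f"{k}={quote(str(v), safe=_SAFE)}" for k, v in pairs)


def _sequence_regions(lengths: Mapping[str, int]) -> List[str]:
    return [f"##sequence-region {sid} 1 {length}" for sid, length in lengths.items()]


def loci_to_gff3(loci: Sequence[SSRLocus], path: PathLike) -> None:
    """One ``microsatellite`` row per locus, with motif and repetitions."""
    lengths: Dict[str, int] = {}
    for locus in loci:
        lengths.setdefault(locus.seq_id, locus.seq_len)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for line in _sequence_regions(lengths):
            handle.write(line + "\n")
        for i, locus in enumerate(
            sorted(loci, key=lambda l: (l.seq_id, l.start, l.unit)), start=1
        ):
            attrs = _attr(
                [
                    ("ID", f"SSR{i:06d}"),
                    ("Name", f"({locus.motif}){locus.repetitions}"),
                    ("motif", locus.motif),
                    ("repetitions", str(locus.repetitions)),
                ]
            )
            handle.write(
                f"{locus.seq_id}\t{SOURCE}\tmicrosatellite\t{locus.start}\t"
                f"{locus.end}\t.\t+\t.\t{attrs}\n"
            )


def markers_to_gff3(
    markers: Sequence[Marker],
    amplicons_on_source: Sequence[Amplicon],
    path: PathLike,
    seq_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """One ``STS`` row per marker placement on its source sequences.

    Placements come from the marker's own amplicons (e-PCR on the source
    genome); a marker with no placement is skipped with a warning.
    Duplicated markers with several placements share a Name.
    """
    by_marker: Dict[str, List[Amplicon]] = {}
    for amp in amplicons_on_source:
        by_marker.setdefault(amp.marker_id, []).append(amp)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        if seq_lengths:
            for line in _sequence_regions(seq_lengths):
                handle.write(line + "\n")
        serial = 0
        for marker in markers:
            placements = by_marker.get(marker.marker_id, [])
            if not placements:
                warnings.warn(
                    f"marker {marker.marker_id} has no source placement; skipped",
                    stacklevel=2,
                )
                continue
            for amp in sorted(placements, key=lambda a: (a.seq_id, a.start)):
                serial += 1
                attrs = _attr(
                    [
                        ("ID", f"STS{serial:06d}"),
                        ("Name", marker.marker_id),
                        ("product_size", str(amp.size)),
                        ("left_primer", marker.pair.left),
                        ("right_primer", marker.pair.right),
                        ("motif", marker.motif),
                    ]
                )
                handle.write(
                    f"{amp.seq_id}\t{SOURCE}\tSTS\t{amp.start}\t{amp.end}\t.\t"
                    f"{amp.strand}\t.\t{attrs}\n"
                )
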