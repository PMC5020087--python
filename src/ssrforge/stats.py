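"""Five statistical classifications of a mined SSR locus table.

The classes are: motif type by unit length, motif composition, complementary
motif groups (a motif and its reverse complement are the same repeat when
strand orientation is unknown), per-sequence SSR frequency, and the SSR
length distribution.  Each table carries a count and a percentage of the
total locus count, ranked descending, and the set is written as the
sectioned ``.sat2`` report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

from .mining import SSRLocus
from .sequence_io import PathLike, SequenceRecord

#: SSRs per million bases; the historical report used 100000 instead.
DEFAULT_FREQ_SCALE = 1_000_000

SECTION_NAMES = [
    "Motif type (unit length)",
    "Motif composition",
    "Complementary motif groups",
    "SSR frequency per sequence",
    "SSR length distribution",
]


class StatsError(ValueError):
    """Inconsistent locus/record input to the statistics module."""


@dataclass
class StatsReport:
    """The five classification tables, in report order."""

    unit_length: pd.DataFrame
    motif: pd.DataFrame
    complement_groups: pd.DataFrame
    frequency: pd.DataFrame
    length: pd.DataFrame

    def tables(self) -> Dict[str, pd.DataFrame]:
        return dict(
            zip(
                SECTION_NAMES,
                [
                    self.unit_length,
                    self.motif,
                    self.complement_groups,
                    self.frequency,
                    self.length,
                ],
            )
        )


def _count_table(values: Iterable, class_column: str) -> pd.DataFrame:
    """Descending-rank count/percentage table over discrete class labels."""
    series = pd.Series(list(values))
    if series.empty:
        return pd.DataFrame(columns=[class_column, "Count", "Percentage"])
    counts = series.value_counts(sort=False)
    total = int(counts.sum())
    df = counts.reset_index()
    df.columns = [class_column, "Count"]
    df["Percentage"] = (100.0 * df["Count"] / total).round(2)
    df = df.sort_values(
        ["Count", class_column], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def classify_unit_length(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Motif-type table: loci counted by unit (motif) length in bp."""
    return _count_table((l.unit for l in loci), "Unit_length")


def classify_motif(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Motif-composition table; motifs counted as reported (phase kept)."""
    return _count_table((l.motif for l in loci), "Motif")


def complement_group(motif: str) -> str:
    """Group label pairing a motif with its reverse complement, e.g. GA/TC.

    The lexicographically smaller word comes first; a self-complementary
    motif such as AT pairs with itself ("AT/AT").
    """
    rc = reverse_complement(motif)
    a, b = sorted([motif.upper(), rc.upper()])
    return f"{a}/{b}"


def group_complementary(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    return _count_table((complement_group(l.motif) for l in loci), "Group")


def per_sequence_frequency(
    loci: Sequence[SSRLocus],
    records: Sequence[SequenceRecord],
    scale: int = DEFAULT_FREQ_SCALE,
) -> pd.DataFrame:
    """Per-sequence SSR counts and frequency = scale * count / length.

    Every record appears, including zero-count ones.  A locus naming a
    sequence absent from ``records`` is an error.
    """
    lengths = {rec.id: rec.length for rec in records}
    counts: Dict[str, int] = {rec.id: 0 for rec in records}
    for locus in loci:
        if locus.seq_id not in lengths:
            raise StatsError(f"locus on unknown sequence {locus.seq_id!r}")
        counts[locus.seq_id] += 1
    rows = [
        {
            "Name": seq_id,
            "Count": counts[seq_id],
            "Length": lengths[seq_id],
            "Frequency": scale * counts[seq_id] / lengths[seq_id],
        }
        for seq_id in lengths
    ]
    df = pd.DataFrame(rows, columns=["Name", "Count", "Length", "Frequency"])
    return df.sort_values(
        ["Count", "Name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def length_distribution(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """SSR-length table: loci counted by total tract length (bp)."""
    return _count_table((l.span for l in loci), "SSR_length")


def compute_stats(
    loci: Sequence[SSRLocus],
    records: Sequence[SequenceRecord],
    scale: int = DEFAULT_FREQ_SCALE,
) -> StatsReport:
    return StatsReport(
        unit_length=classify_unit_length(loci),
        motif=classify_motif(loci),
        complement_groups=group_complementary(loci),
        frequency=per_sequence_frequency(loci, records, scale),
        length=length_distribution(loci),
    )


def write_sat2(report: StatsReport, path: PathLike) -> None:
    """Write the five tables as a sectioned tab-separated report."""
    with open(path, "w") as handle:
        for name, table in report.tables().items():
            handle.write(f"# {name}\n")
            handle.write("\t".join(table.columns) + "\n")
            # itertuples keeps per-column dtypes (iterrows would float-cast)
            for row in table.itertuples(index=False):
                handle.write("\t".join(_fmt(v) for v in row) + "\n")
            handle.write("\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return repr(float(value))  # shortest representation that round-trips
    return str(value)


def read_sat2(path: PathLike) -> StatsReport:
    """Parse a ``.sat2`` report back into tables (numeric where possible)."""
    sections: Dict[str, pd.DataFrame] = {}
    with open(path) as handle:
        name: Optional[str] = None
        header: Optional[List[str]] = None
        rows: List[List[str]] = []
        for raw in list(handle) + ["\n"]:
            line = raw.rstrip("\r\n")
            if line.startswith("# "):
                name = line[2:]
                header, rows = None, []
            elif line and header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
            elif name is not None and header is not None:
                df = pd.DataFrame(rows, columns=header)
                for col in df.columns[1:]:
                    df[col] = pd.to_numeric(df[col])
                if name == SECTION_NAMES[0] or name == SECTION_NAMES[4]:
                    df[df.columns[0]] = pd.to_numeric(df[df.columns[0]])
                sections[name] = df
                name, header, rows = None, None, []
    missing = [s for s in SECTION_NAMES if s not in sections]
    if missing:
        raise StatsError(f"{path}: missing sections {missing}")
    return StatsReport(
        unit_length=sections[SECTION_NAMES[0]],
        motif=sections[SECTION_NAMES[1]],
        complement_groups=sections[SECTION_NAMES[2]],
        frequency=sections[SECTION_NAMES[3]],
        length=sections[SECTION_NAMES[4]],
    )
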