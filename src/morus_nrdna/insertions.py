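"""Regex read counting for the 13/16 bp ITS1 insertion at nrDNA 1862.

Reads spanning the insertion locus are classified by fixed flank patterns:
an insertion-supporting read shows the inserted tail ``AATGCG`` directly
against the downstream flank (``TCGAAACC.+AATGCGCCCCAACCCC`` on the plus
strand, or its reverse-complement rendering
``GGGGTTGGGGCGCATT.+GGTTTCGA``); a reference-supporting read shows the
flanks without the inserted bases.  Every insertion-matching read also
matches the looser reference pattern, so insertion takes precedence.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

ReadClass = Literal["ins", "ref", "neither"]
TallyStatus = Literal["ins_only", "ref_only", "mixed", "nocall"]

INS_FORWARD = "TCGAAACC.+AATGCGCCCCAACCCC"
INS_REVERSE = "GGGGTTGGGGCGCATT.+GGTTTCGA"
REF_FORWARD = "TCGAAACC.+CCCCAACCCC"
REF_REVERSE = "GGGGTTGGGG.+GGTTTCGA"


@dataclass(frozen=True)
class InsertionPatterns:
    """The two orientation-specific pattern pairs, compiled once."""

    ins_forward: str = INS_FORWARD
    ins_reverse: str = INS_REVERSE
    ref_forward: str = REF_FORWARD
    ref_reverse: str = REF_REVERSE
    _compiled: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_compiled",
            (
                re.compile(self.ins_forward),
                re.compile(self.ins_reverse),
                re.compile(self.ref_forward),
                re.compile(self.ref_reverse),
            ),
        )

    @property
    def compiled(self):
        return self._compiled


DEFAULT_PATTERNS = InsertionPatterns()


@dataclass(frozen=True)
class ReadTally:
    """Classified read counts for one accession."""

    n_ins: int
    n_ref: int
    n_total: int
    status: TallyStatus

    def __post_init__(self) -> None:
        if self.n_ins + self.n_ref > self.n_total:
            raise ValueError("classified reads exceed total reads")


def classify_read(
    read: str, patterns: InsertionPatterns = DEFAULT_PATTERNS
) -> ReadClass:
    """'ins' if either insertion pattern matches, else 'ref', else 'neither'."""
    seq = read.upper()
    ins_f, ins_r, ref_f, ref_r = patterns.compiled
    if ins_f.search(seq) or ins_r.search(seq):
        return "ins"
    if ref_f.search(seq) or ref_r.search(seq):
        return "ref"
    return "neither"


def tally_reads(
    reads: Iterable[str],
    patterns: InsertionPatterns = DEFAULT_PATTERNS,
    min_reads: int = 1,
) -> ReadTally:
    """Count read classes and call the accession's allele status.

    Status is ``mixed`` when both sides reach ``min_reads`` supporting
    reads, ``ins_only``/``ref_only`` when only one side does, ``nocall``
    otherwise (including an empty read list).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    n_ins = n_ref = n_total = 0
    for read in reads:
        n_total += 1
        cls = classify_read(read, patterns)
        if cls == "ins":
            n_ins += 1
        elif cls == "ref":
            n_ref += 1
    if n_ins >= min_reads and n_ref >= min_reads:
        status: TallyStatus = "mixed"
    elif n_ins >= min_reads:
        status = "ins_only"
    elif n_ref >= min_reads:
        status = "ref_only"
    else:
        status = "nocall"
    return ReadTally(n_ins, n_ref, n_total, status)


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip-aware)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq)


def write_tally_report(
    tallies: Sequence[tuple[str, ReadTally]], path: str | Path
) -> None:
    """Tab-delimited per-accession report: id, n_ins, n_ref, n_total, status."""
    with open(path, "w") as fh:
        fh.write("accession_id\tn_ins\tn_ref\tn_total\tstatus\n")
        for accession_id, t in tallies:
            fh.write(
                f"{accession_id}\t{t.n_ins}\t{t.n_ref}\t{t.n_total}\t{t.status}\n"
            )
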