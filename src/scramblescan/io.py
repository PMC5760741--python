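"""FASTA and tabular-hit I/O.

FASTA goes through Biopython. Hits use the 12-column tabular dialect
(query, subject, %identity, length, mismatches, gapopen, qstart, qend,
sstart, send, evalue, bitscore) with 1-based inclusive coordinates and a
reversed subject interval encoding the minus strand; gapopen is always 0 and
evalue/bitscore may be "NA". Everything in memory is 0-based half-open with
an explicit strand.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | os.PathLike, records: Mapping[str, str]) -> str:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items())
    SeqIO.write(recs, str(path), "fasta")
    return str(path)


def write_hits(path: str | os.PathLike, hsps: Iterable) -> str:
    """Write Hsp records in the 12-column tabular dialect."""
    with open(path, "w") as fh:
        for h in hsps:
            qstart, qend = h.t_start + 1, h.t_end
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            mism = h.length - round(h.percent_identity / 100.0 * h.length)
            fh.write(
                "\t".join(
                    [
                        h.transcript_id,
                        h.scaffold_id,
                        f"{h.percent_identity:.2f}",
                        str(h.length),
                        str(mism),
                        "0",
                        str(qstart),
                        str(qend),
                        str(sstart),
                        str(send),
                        "NA",
                        "NA",
                    ]
                )
                + "\n"
            )
    return str(path)


def read_hits(path: str | os.PathLike) -> list:
    """Read 12-column tabular hits into Hsp records (strand decoded)."""
    from .mapping import Hsp  # local import to avoid a cycle

    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise InputError(f"{path}:{lineno}: expected 12 columns")
            qid, sid, pid, length = fields[0], fields[1], float(fields[2]), int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            if qstart > qend:
                raise InputError(f"{path}:{lineno}: query interval must be forward")
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            hsps.append(
                Hsp(
                    transcript_id=qid,
                    scaffold_id=sid,
                    t_start=qstart - 1,
                    t_end=qend,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    percent_identity=pid,
                    length=length,
                )
            )
    return hsps
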