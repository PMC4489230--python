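"""Alignment readers and writers.

Reads CLUSTAL, FASTA, MSF, Phylip (interleaved or sequential, strict or
relaxed names) and Nexus; writes CLUSTAL, FASTA and Phylip, plus the
multi-dataset sequential Phylip used to feed bootstrap replicates to tree
programs as "multiple data sets".  Parsing of the standard single-alignment
formats is delegated to Bio.AlignIO; the multi-dataset Phylip dialect and
the relaxed Phylip writer are local because Biopython has no equivalent.

Normalisation on read: residues are upper-cased and the '.' and '~' gap
dialects become '-'.  Format sniffing checks unambiguous magics first:
Nexus, CLUSTAL, MSF, Phylip header, then FASTA.
"""

from __future__ import annotations

import io
import os
import re
from typing import IO, Iterable, Sequence as Seq, Union

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq as BioSeq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment
from .errors import AlignmentFormatError, MalformedAlignmentError

READ_FORMATS = ("fasta", "clustal", "msf", "phylip", "nexus")
WRITE_FORMATS = ("clustal", "fasta", "phylip")

_GAP_TRANS = str.maketrans({".": "-", "~": "-"})

Source = Union[str, os.PathLike, IO[str]]


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode() if isinstance(data, bytes) else data
    with open(source, "r") as fh:
        return fh.read()


def sniff_format(text: str) -> str:
    """Guess the alignment format from content; raise if nothing matches."""
    stripped = text.lstrip()
    if not stripped:
        raise AlignmentFormatError("empty input")
    upper = stripped.upper()
    if upper.startswith("#NEXUS"):
        return "nexus"
    if upper.startswith("CLUSTAL"):
        return "clustal"
    head = "\n".join(stripped.splitlines()[:20]).upper()
    if "!!AA_MULTIPLE_ALIGNMENT" in head or "!!NA_MULTIPLE_ALIGNMENT" in head \
            or re.search(r"\bMSF:", head):
        return "msf"
    first = stripped.splitlines()[0].split()
    if len(first) == 2 and all(tok.isdigit() for tok in first):
        return "phylip"
    if stripped.startswith(">"):
        return "fasta"
    raise AlignmentFormatError("could not detect alignment format")


def _from_biopython(msa: MultipleSeqAlignment) -> Alignment:
    names = [rec.id for rec in msa]
    rows = [str(rec.seq).upper().translate(_GAP_TRANS) for rec in msa]
    return Alignment(names, rows)


def _parse_rows_generic(text: str, fmt: str) -> Alignment:
    """Parse via AlignIO but detect ragged FASTA rows ourselves for a clear error."""
    if fmt == "fasta":
        from Bio import SeqIO
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise AlignmentFormatError("no FASTA records found")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"FASTA rows have unequal lengths: {sorted(lengths)}")
        names = [r.id for r in records]
        rows = [str(r.seq).upper().translate(_GAP_TRANS) for r in records]
        return Alignment(names, rows)
    if fmt == "phylip":
        return _parse_phylip_any(text)
    try:
        msa = AlignIO.read(io.StringIO(text), fmt)
    except MalformedAlignmentError:
        raise
    except Exception as exc:  # Biopython raises bare ValueError liberally
        raise AlignmentFormatError(f"failed to parse as {fmt}: {exc}") from exc
    return _from_biopython(msa)


def _parse_phylip_any(text: str) -> Alignment:
    """Accept strict/relaxed, interleaved/sequential Phylip."""
    for fmt in ("phylip-relaxed", "phylip-sequential", "phylip"):
        try:
            return _from_biopython(AlignIO.read(io.StringIO(text), fmt))
        except Exception:
            continue
    try:  # relaxed sequential: one "name sequence" line per sequence
        return _parse_relaxed_sequential(text)
    except Exception as exc:
        raise AlignmentFormatError(f"failed to parse Phylip content: {exc}") from exc


def _parse_relaxed_sequential(text: str) -> Alignment:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n, length = (int(tok) for tok in lines[0].split()[:2])
    names, rows = [], []
    for ln in lines[1 : 1 + n]:
        name, *chunks = ln.split()
        names.append(name)
        rows.append("".join(chunks).upper().translate(_GAP_TRANS))
    if len(rows) != n or any(len(r) != length for r in rows):
        raise MalformedAlignmentError("Phylip body does not match its header")
    return Alignment(names, rows)


def read_alignment(source: Source, format: str | None = None) -> Alignment:
    """Read one alignment from a path or text stream.

    Parameters
    ----------
    source:
        File path or readable text/binary stream containing the alignment.
    format:
        One of ``fasta/clustal/msf/phylip/nexus``; sniffed when omitted.
    """
    text = _read_text(source)
    fmt = (format or sniff_format(text)).lower()
    if fmt not in READ_FORMATS:
        raise AlignmentFormatError(f"unsupported read format {fmt!r}")
    return _parse_rows_generic(text, fmt)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _to_biopython(aln: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(BioSeq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows))


def _phylip_names(aln: Alignment, strict: bool) -> list[str]:
    if not strict:
        return list(aln.names)
    truncated = [name[:10] for name in aln.names]
    dupes = {t for t in truncated if truncated.count(t) > 1}
    if dupes:
        raise MalformedAlignmentError(
            f"strict-Phylip truncation collides on names: {sorted(dupes)}")
    return truncated


def _format_phylip(aln: Alignment, strict: bool = False) -> str:
    names = _phylip_names(aln, strict)
    width = max(10, max(len(n) for n in names)) + 2
    lines = [f" {aln.n} {aln.length}"]
    for name, row in zip(names, aln.rows):
        lines.append(f"{name:<{width}}{row}")
    return "\n".join(lines) + "\n"


def _format_fasta(aln: Alignment, wrap: int = 60) -> str:
    parts = []
    for name, row in zip(aln.names, aln.rows):
        parts.append(f">{name}")
        parts.extend(row[i : i + wrap] for i in range(0, len(row), wrap))
    return "\n".join(parts) + "\n"


def write_alignment(aln: Alignment, format: str, sink: Source,
                    strict_phylip: bool = False) -> None:
    """Write an alignment as CLUSTAL, FASTA or (relaxed/strict) Phylip.

    Round-trip contract: ``read_alignment`` on the written text reproduces
    names, order and residues exactly (strict Phylip excepted when names
    exceed 10 characters, where truncation applies and collisions raise).
    """
    fmt = format.lower()
    if fmt not in WRITE_FORMATS:
        raise AlignmentFormatError(f"unsupported write format {fmt!r}")
    if fmt == "clustal":
        buf = io.StringIO()
        AlignIO.write(_to_biopython(aln), buf, "clustal")
        text = buf.getvalue()
    elif fmt == "fasta":
        text = _format_fasta(aln)
    else:
        text = _format_phylip(aln, strict=strict_phylip)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def write_phylip_multidataset(replicates: Iterable[Alignment] | "ReplicateSet",
                              sink: Source) -> None:
    """Write replicate alignments as concatenated sequential-Phylip datasets.

    The output is directly usable where a tree program expects multiple data
    sets in one Phylip file (one ``N L`` header per dataset).
    """
    alns: Seq[Alignment] = list(getattr(replicates, "replicates", replicates))
    if not alns:
        raise MalformedAlignmentError("empty replicate set")
    n, length = alns[0].n, alns[0].length
    for a in alns:
        if a.n != n or a.length != length:
            raise MalformedAlignmentError("replicates differ in N or L")
    text = "".join(_format_phylip(a) for a in alns)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def read_phylip_multidataset(source: Source) -> list[Alignment]:
    """Parse a multi-dataset sequential Phylip file back into alignments."""
    lines = [ln for ln in _read_text(source).splitlines() if ln.strip()]
    out: list[Alignment] = []
    i = 0
    while i < len(lines):
        header = lines[i].split()
        if len(header) < 2 or not all(tok.isdigit() for tok in header[:2]):
            raise AlignmentFormatError(f"expected Phylip header at line {i + 1}")
        n = int(header[0])
        out.append(_parse_relaxed_sequential("\n".join(lines[i : i + n + 1])))
        i += n + 1
    if not out:
        raise AlignmentFormatError("no datasets found")
    return out
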