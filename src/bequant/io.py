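"""File-format plumbing: FASTA, FASTQ (plain/gzip), minimal VCF, TSV."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .goti import SNVCall, SNVCallSet


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime keeps outputs byte-identical across reruns
            return _DeterministicGzipText(path)
        return gzip.open(path, mode)
    return open(path, mode)


class _DeterministicGzipText:
    """Text-mode gzip writer with a fixed mtime (reproducible bytes)."""

    def __init__(self, path: Path):
        import io as _io
        self._raw = open(path, "wb")
        self._gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw,
                                 mtime=0)
        self._txt = _io.TextIOWrapper(self._gz, encoding="ascii",
                                      newline="\n")

    def __enter__(self):
        return self._txt

    def __exit__(self, *exc):
        self._txt.flush()
        self._txt.close()
        self._raw.close()
        return False


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs; transparently handles .gz."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality: int = 40) -> None:
    """Write (read_id, sequence) pairs with a constant quality score."""
    with _open_text(path, "wt") as handle:
        for read_id, seq in reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            SeqIO.write(rec, handle, "fastq")


def write_vcf(callset: SNVCallSet, path: str | Path,
              reference: str = ".") -> None:
    """Minimal VCF 4.2 with DP/AD/AF in the INFO column."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference}",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">',
        '##INFO=<ID=CAD,Number=1,Type=Integer,'
        'Description="Control alt depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    calls = sorted(callset, key=lambda c: (c.chrom, c.pos, c.alt))
    for c in calls:
        info = f"DP={c.depth};AD={c.alt_depth};AF={c.af:.4f};CAD={c.control_alt_depth}"
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snvs(path: str | Path, name: str = "") -> SNVCallSet:
    """Read an SNV set from TSV (chrom/pos/ref/alt columns) or VCF."""
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF
        calls = []
        for v in VCF(str(path)):
            info = dict(v.INFO)
            for alt in v.ALT:
                calls.append(SNVCall(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    alt_depth=int(info.get("AD", 0)),
                    depth=int(info.get("DP", 0)),
                    af=float(info.get("AF", float("nan"))),
                    control_alt_depth=int(info.get("CAD", 0))))
        return SNVCallSet(calls, name=name or path.stem)
    return SNVCallSet.from_tsv(path, name=name or path.stem)
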