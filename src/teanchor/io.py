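"""Readers and writers for the text formats the pipeline touches.

Every reader emits 0-based half-open coordinates regardless of the
source convention: BED-family inputs already are, RepeatMasker ``.out``
(1-based inclusive) and chain files are converted here and nowhere else.
Chromosome names are matched exactly; no "chr" prefix munging.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ChainAlignment,
    ChainBlock,
    ChromStateSegment,
    GenomeAssembly,
    GenomicInterval,
    Loop,
    Peak,
    PeakSet,
    RepeatFeature,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input row; message carries the file and line number."""


def _check_chrom(chrom: str, assembly: Optional[GenomeAssembly], path, lineno: int) -> None:
    if assembly is not None and chrom not in assembly:
        raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r} "
                         f"for assembly {assembly.name!r}")


# ---------------------------------------------------------------------------
# chrom.sizes

def read_chrom_sizes(path, name: str = "assembly") -> GenomeAssembly:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            chrom, size = fields[0], int(fields[1])
            if chrom in sizes:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = size
    return GenomeAssembly(name=name, chrom_sizes=sizes)


def write_chrom_sizes(assembly: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in assembly.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# BEDPE loops

def read_bedpe_loops(path, assembly: Optional[GenomeAssembly] = None,
                     resolution: int = 0) -> list[Loop]:
    """Read loop calls from a >=6-column BEDPE file.

    Anchors are swapped into genome order; inter-chromosomal rows are
    skipped with a logged warning.  When no id column (7) is present a
    stable id is synthesized from the anchor coordinates.
    """
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BEDPE needs >=6 columns, got {len(fields)}")
            try:
                c1, s1, e1, c2, s2, e2 = (fields[0], int(fields[1]), int(fields[2]),
                                          fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            _check_chrom(c1, assembly, path, lineno)
            _check_chrom(c2, assembly, path, lineno)
            if c1 != c2:
                logger.warning("%s:%d: skipping inter-chromosomal loop %s/%s", path, lineno, c1, c2)
                continue
            loop_id = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
            a1 = GenomicInterval(c1, s1, e1)
            a2 = GenomicInterval(c2, s2, e2)
            loops.append(Loop.make(a1, a2, id=loop_id, resolution=resolution))
    return loops


def write_bedpe_loops(loops: Iterable[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write("\t".join(map(str, (
                lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end,
                lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end,
                lp.id))) + "\n")


def deduplicate_loops(loops: Iterable[Loop], resolution: int = 0
                      ) -> tuple[list[Loop], list[tuple[str, str]]]:
    """Drop loops with identical anchor coordinates; flag near-duplicates.

    Returns (unique loops, list of (kept_id, near_duplicate_id) pairs for
    loop pairs whose both anchors start within one ``resolution`` unit).
    """
    seen: dict[tuple, Loop] = {}
    for lp in loops:
        key = (lp.chrom, lp.anchor1.start, lp.anchor1.end, lp.anchor2.start, lp.anchor2.end)
        seen.setdefault(key, lp)
    unique = list(seen.values())
    near: list[tuple[str, str]] = []
    if resolution > 0:
        for i, a in enumerate(unique):
            for b in unique[i + 1:]:
                if (a.chrom == b.chrom
                        and abs(a.anchor1.start - b.anchor1.start) <= resolution
                        and abs(a.anchor2.start - b.anchor2.start) <= resolution):
                    near.append((a.id, b.id))
    return unique, near


# ---------------------------------------------------------------------------
# BED / narrowPeak / ChromHMM

def read_bed(path, assembly: Optional[GenomeAssembly] = None) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            _check_chrom(chrom, assembly, path, lineno)
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(path, label: str = "CTCF",
                    assembly: Optional[GenomeAssembly] = None) -> PeakSet:
    """ENCODE narrowPeak: BED6+4; the signalValue column (7) is the score."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            _check_chrom(chrom, assembly, path, lineno)
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[6]) if len(fields) > 6 else (
                float(fields[4]) if len(fields) > 4 else 0.0)
            peaks.append(Peak(GenomicInterval(chrom, start, end), score=score, name=name))
    return PeakSet(peaks=peaks, label=label)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            fh.write("\t".join(map(str, (
                iv.chrom, iv.start, iv.end, p.name, 0, ".", p.score, -1, -1, -1))) + "\n")


def read_chromhmm_bed(path, assembly: Optional[GenomeAssembly] = None
                      ) -> list[ChromStateSegment]:
    """BED4 with the ChromHMM state label in column 4."""
    segments: list[ChromStateSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: ChromHMM BED needs >=4 columns")
            chrom, start, end, state = fields[0], int(fields[1]), int(fields[2]), fields[3]
            _check_chrom(chrom, assembly, path, lineno)
            segments.append(ChromStateSegment(GenomicInterval(chrom, start, end), state))
    return segments


def write_chromhmm_bed(segments: Iterable[ChromStateSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

def read_repeatmasker_out(path, assembly: Optional[GenomeAssembly] = None
                          ) -> list[RepeatFeature]:
    """Parse a RepeatMasker ``.out`` table.

    Layout: 3 header lines, whitespace-separated columns; query begin/end
    (cols 6-7) are 1-based inclusive and converted to 0-based half-open;
    column 11 is "class/family" which is split on the first "/"
    (family = class when there is no slash); column 10 is the repeat
    (subfamily) name; column 9 is the strand ('+' or 'C').
    """
    repeats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            # header lines start with "SW"/"score" or "bit"
            if fields[0] in ("SW", "score", "bit"):
                continue
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: RepeatMasker row has {len(fields)} columns")
            try:
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                subfamily = fields[9]
                class_family = fields[10]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            _check_chrom(chrom, assembly, path, lineno)
            if "/" in class_family:
                class_name, family = class_family.split("/", 1)
            else:
                class_name = family = class_family
            if not class_name:
                logger.warning("%s:%d: unsplittable class/family %r", path, lineno, class_family)
                class_name = family = class_family or "Unknown"
            repeats.append(RepeatFeature(
                interval=GenomicInterval(chrom, begin - 1, end, strand),
                subfamily=subfamily, family=family, class_name=class_name))
    return repeats


def write_repeatmasker_out(repeats: Iterable[RepeatFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query      position in query     matching"
                 "  repeat          position in  repeat\n")
        fh.write("score  div. del. ins.  sequence    begin     end    (left)"
                 "   repeat        class/family  begin  end (left)   ID\n\n")
        for i, rep in enumerate(repeats, 1):
            iv = rep.interval
            cf = rep.class_name if rep.class_name == rep.family else f"{rep.class_name}/{rep.family}"
            strand = "C" if iv.strand == "-" else "+"
            fh.write(f"  225  10.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}  (0)  "
                     f"{strand}  {rep.subfamily}  {cf}  1  {iv.length}  (0)  {i}\n")


# ---------------------------------------------------------------------------
# UCSC chain

def read_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; chains are returned sorted by score, descending.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; the t-side is the lift *source* and the
    q-side the *target*.  A declared span that disagrees with the block
    walk raises a :class:`ParseError` naming the chain id.
    """
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        lines = iter(enumerate(fh, 1))
        for lineno, line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not line.startswith("chain"):
                raise ParseError(f"{path}:{lineno}: expected chain header, got {line!r}")
            fields = line.split()
            if len(fields) != 13:
                raise ParseError(f"{path}:{lineno}: chain header needs 13 fields")
            (_, score, t_name, t_size, t_strand, t_start, t_end,
             q_name, q_size, q_strand, q_start, q_end, chain_id) = fields
            blocks: list[ChainBlock] = []
            for lineno2, bline in lines:
                bline = bline.strip()
                if not bline:
                    break
                parts = bline.split()
                if len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0])))
                    break
                elif len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ParseError(f"{path}:{lineno2}: bad chain block {bline!r}")
            try:
                chains.append(ChainAlignment(
                    chain_id=chain_id, score=float(score),
                    source_chrom=t_name, source_size=int(t_size), source_strand=t_strand,
                    source_start=int(t_start), source_end=int(t_end),
                    target_chrom=q_name, target_size=int(q_size), target_strand=q_strand,
                    target_start=int(q_start), target_end=int(q_end),
                    blocks=tuple(blocks)))
            except ValueError as exc:
                raise ParseError(f"{path}: chain {chain_id}: {exc}") from None
    chains.sort(key=lambda c: -c.score)
    return chains


def write_chain(chains: Iterable[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(" ".join(map(str, (
                "chain", int(ch.score) if ch.score == int(ch.score) else ch.score,
                ch.source_chrom, ch.source_size, ch.source_strand,
                ch.source_start, ch.source_end,
                ch.target_chrom, ch.target_size, ch.target_strand,
                ch.target_start, ch.target_end, ch.chain_id))) + "\n")
            for b in ch.blocks[:-1]:
                fh.write(f"{b.size}\t{b.source_gap}\t{b.target_gap}\n")
            fh.write(f"{ch.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV reports

def write_tsv_report(df: pd.DataFrame, path, header_comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with optional '#'-prefixed header lines."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
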