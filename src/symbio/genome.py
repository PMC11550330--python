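"""Genome composition and symbiont-load utilities.

Coordinates are 1-based inclusive (GFF3 convention) throughout.  A+T content
is computed over unambiguous bases only (N excluded from the denominator,
case-insensitive); introns are the gaps between consecutive exons of a
transcript, optionally checked for canonical GT-AG splice boundaries on the
transcript strand.  Symbiont load per host cell is estimated from the ratio
of mean symbiont to mean host-nuclear sequencing depth times host ploidy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple  # ((start, end), ...) 1-based inclusive, sorted by start

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon {start}-{end} reversed")
            if start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping or unsorted exons"
                )
            prev_end = end


@dataclass(frozen=True)
class Intron:
    transcript_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    gt_ag: Optional[bool] = None  # canonical boundary on the transcript strand

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Contig sequences plus transcript models."""

    contigs: Dict[str, str]
    transcripts: Dict[str, Transcript] = field(default_factory=dict)

    def __post_init__(self):
        self.contigs = {k: v.upper() for k, v in self.contigs.items()}
        for t in self.transcripts.values():
            if t.contig not in self.contigs:
                raise ValueError(f"{t.transcript_id}: unknown contig {t.contig}")
            clen = len(self.contigs[t.contig])
            for start, end in t.exons:
                if start < 1 or end > clen:
                    raise ValueError(
                        f"{t.transcript_id}: exon {start}-{end} outside contig "
                        f"{t.contig} (length {clen})"
                    )

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of a 1-based inclusive interval on the plus strand."""
        return self.contigs[contig][start - 1 : end]


def _check_alphabet(seq: str, contig: str) -> None:
    bad = [i + 1 for i, b in enumerate(seq) if b not in _VALID]
    if bad:
        shown = bad[:10]
        raise ValueError(
            f"contig {contig}: non-ACGTN bases at positions {shown}"
            + ("..." if len(bad) > 10 else "")
        )


def at_content(
    contigs: Mapping[str, str],
    mask: Optional[Iterable[Tuple[str, int, int]]] = None,
) -> float:
    """(A+T)/(A+C+G+T) over the selected bases, N excluded, strand-agnostic.

    ``mask`` optionally restricts the computation to a set of
    (contig, start, end) intervals, 1-based inclusive; otherwise all bases of
    all contigs are used.  Rejects ambiguity codes other than N.
    """
    if mask is None:
        selected = [(c, seq) for c, seq in contigs.items()]
    else:
        selected = []
        for contig, start, end in mask:
            if contig not in contigs:
                raise ValueError(f"mask references unknown contig {contig}")
            if start < 1 or end > len(contigs[contig]) or start > end:
                raise ValueError(f"mask interval {contig}:{start}-{end} out of bounds")
            selected.append((contig, contigs[contig][start - 1 : end]))
    at = informative = 0
    for contig, seq in selected:
        seq = seq.upper()
        _check_alphabet(seq, contig)
        at += seq.count("A") + seq.count("T")
        informative += len(seq) - seq.count("N")
    if informative == 0:
        raise ValueError("empty selection: no unambiguous bases")
    return at / informative


def extract_introns(genome: AnnotatedGenome, check_gt_ag: bool = True) -> List[Intron]:
    """Introns of every transcript, with an optional GT-AG boundary report.

    An intron is the gap between two consecutive exons; adjacent exons
    (zero-length gap) yield no intron.  The GT-AG check is strand-aware and
    reported per intron, never enforced.
    """
    introns: List[Intron] = []
    for tid in sorted(genome.transcripts):
        t = genome.transcripts[tid]
        for (s1, e1), (s2, _e2) in zip(t.exons, t.exons[1:]):
            start, end = e1 + 1, s2 - 1
            if start > end:
                continue  # zero-length gap: exons are adjacent
            gt_ag = None
            if check_gt_ag:
                seq = genome.fetch(t.contig, start, end)
                if t.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                gt_ag = len(seq) >= 4 and seq[:2] == "GT" and seq[-2:] == "AG"
            introns.append(
                Intron(
                    transcript_id=tid,
                    contig=t.contig,
                    start=start,
                    end=end,
                    strand=t.strand,
                    gt_ag=gt_ag,
                )
            )
    return introns


def intron_at_content(genome: AnnotatedGenome) -> float:
    """A+T content restricted to intron sequence."""
    introns = extract_introns(genome, check_gt_ag=False)
    if not introns:
        raise ValueError("genome has no introns")
    return at_content(genome.contigs, mask=[(i.contig, i.start, i.end) for i in introns])


COVERAGE_BINS = ("host_nuclear", "symbiont", "other")


@dataclass(frozen=True)
class SymbiontLoad:
    """Point estimate plus contig-level spread of the symbiont load."""

    load: float  # symbiont genome copies per host nuclear genome
    host_depth: float
    symbiont_depth: float
    contig_loads_sd: float  # sd of per-contig symbiont-depth-based loads

    def __float__(self) -> float:
        return self.load


def read_coverage(path) -> pd.DataFrame:
    """Read a coverage TSV with columns contig, length, mean_depth, bin."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "length", "mean_depth", "bin"}
    if not required.issubset(df.columns):
        raise ValueError(f"coverage table must have columns {sorted(required)}")
    if (df["mean_depth"] < 0).any():
        raise ValueError("mean_depth must be >= 0")
    bad = df.loc[~df["bin"].isin(COVERAGE_BINS)]
    if len(bad):
        raise ValueError(f"unknown bin labels: {sorted(set(bad['bin']))}")
    return df


def symbiont_load(
    cov: pd.DataFrame,
    host_ploidy: float = 1.0,
    length_weighting: bool = True,
) -> SymbiontLoad:
    """Symbiont genome copies per host genome from relative sequencing depth.

    load = (mean symbiont depth / mean host-nuclear depth) x host_ploidy,
    with per-contig depths averaged length-weighted by default (a per-base
    mean).  The host nuclear ploidy is a multiplier supplied by the caller
    (the published estimates posit a haploid host).
    """
    if host_ploidy < 1:
        raise ValueError("host_ploidy must be >= 1")
    sym = cov.loc[cov["bin"] == "symbiont"]
    host = cov.loc[cov["bin"] == "host_nuclear"]
    if sym.empty or host.empty:
        raise ValueError("need at least one contig in each of host_nuclear and symbiont")

    def mean_depth(df: pd.DataFrame) -> float:
        if length_weighting:
            return float(np.average(df["mean_depth"], weights=df["length"]))
        return float(df["mean_depth"].mean())

    host_d = mean_depth(host)
    if host_d == 0:
        raise ValueError("host nuclear depth is zero")
    sym_d = mean_depth(sym)
    per_contig = sym["mean_depth"].to_numpy() / host_d * host_ploidy
    return SymbiontLoad(
        load=sym_d / host_d * host_ploidy,
        host_depth=host_d,
        symbiont_depth=sym_d,
        contig_loads_sd=float(np.std(per_contig)),
    )


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_genome(fasta_path, gff3_path) -> AnnotatedGenome:
    """Load contigs (FASTA) and transcript models (GFF3, exon features with
    Parent links) into an :class:`AnnotatedGenome`."""
    import gffutils

    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: Dict[str, Transcript] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (e.start, e.end) for e in db.children(mrna, featuretype="exon")
        )
        if not exons:
            continue
        transcripts[mrna.id] = Transcript(
            transcript_id=mrna.id,
            contig=mrna.seqid,
            strand=mrna.strand if mrna.strand in "+-" else "+",
            exons=tuple(exons),
        )
    return AnnotatedGenome(contigs=contigs, transcripts=transcripts)


def write_genome(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    with open(fasta_path, "w") as fh:
        for cid in sorted(genome.contigs):
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in sorted(genome.transcripts):
            t = genome.transcripts[tid]
            span = (t.exons[0][0], t.exons[-1][1])
            fh.write(
                f"{t.contig}\tsymbio\tgene\t{span[0]}\t{span[1]}\t.\t{t.strand}\t.\t"
                f"ID=gene_{tid}\n"
            )
            fh.write(
                f"{t.contig}\tsymbio\tmRNA\t{span[0]}\t{span[1]}\t.\t{t.strand}\t.\t"
                f"ID={tid};Parent=gene_{tid}\n"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.contig}\tsymbio\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
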