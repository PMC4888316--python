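"""Rule-based annotation of CNV events against gene and QTL tracks.

Gene overlap is any shared basepair (1-based inclusive arithmetic:
overlap = min(ends) - max(starts) + 1).  Each overlap's geometry is
classified: a gene fully inside the event is ``gene-within-cnv``; an event
touching at least one exon is ``exon-overlap``; an event inside the gene
body touching no exon is ``intron-contained``; anything else is
``partial``.  Promoter scanning uses a fixed window upstream of the TSS
(strand-aware, default 2 kb).  QTL overlap first discards QTLs whose
confidence-interval span exceeds 30 Mb, then requires at least half of the
CNV's length to be covered by a single QTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["cnv", "partner", "kind", "geometry",
                  "overlap_bp", "cnv_coverage_fraction"]


@dataclass
class GeneRecord:
    symbol: str
    chromosome: str
    strand: str
    tx_start: int  # 1-based inclusive
    tx_end: int
    exons: list = field(default_factory=list)  # [(start, end)] 1-based inclusive

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(map(int, e)) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or e < s:
                raise ValueError(f"exon ({s}, {e}) outside gene {self.symbol}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"overlapping exons in gene {self.symbol}")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class QtlRecord:
    qtl_id: str
    phenotype: str
    chromosome: str
    ci_start: int  # 1-based inclusive confidence-interval span
    ci_end: int

    def __post_init__(self):
        if self.ci_end < self.ci_start:
            raise ValueError(f"QTL {self.qtl_id}: ci_end < ci_start")

    @property
    def ci_length(self) -> int:
        return self.ci_end - self.ci_start + 1


def overlap_bp(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Shared basepairs of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(end_a, end_b) - max(start_a, start_b) + 1)


# ---------------------------------------------------------------------------
# genePred / GFF3 track I/O

GENEPRED_COLUMNS = ["name", "chrom", "strand", "txStart", "txEnd",
                    "exonCount", "exonStarts", "exonEnds"]


def read_genepred(path) -> list[GeneRecord]:
    """Read a genePred-style TSV (0-based half-open on disk, converted)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GENEPRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genePred file missing columns: {missing}")
    genes = []
    for _, r in df.iterrows():
        starts = [int(x) for x in str(r["exonStarts"]).rstrip(",").split(",") if x]
        ends = [int(x) for x in str(r["exonEnds"]).rstrip(",").split(",") if x]
        genes.append(GeneRecord(
            symbol=str(r["name"]), chromosome=str(r["chrom"]),
            strand=str(r["strand"]),
            tx_start=int(r["txStart"]) + 1, tx_end=int(r["txEnd"]),
            exons=[(s + 1, e) for s, e in zip(starts, ends)],
        ))
    return genes


def write_genepred(genes: list[GeneRecord], path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "name": g.symbol, "chrom": g.chromosome, "strand": g.strand,
            "txStart": g.tx_start - 1, "txEnd": g.tx_end,
            "exonCount": len(g.exons),
            "exonStarts": ",".join(str(s - 1) for s, _ in g.exons) + ",",
            "exonEnds": ",".join(str(e) for _, e in g.exons) + ",",
        })
    pd.DataFrame(rows, columns=GENEPRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qtl_gff3(path) -> list[QtlRecord]:
    """Read an Animal-QTLdb-style GFF3 dump (QTL span as the feature span)."""
    qtls = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]}")
            chrom, _, _, start, end, _, _, _, attrs = parts[:9]
            kv = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.strip()] = v.strip()
            qtls.append(QtlRecord(
                qtl_id=kv.get("ID", f"QTL{len(qtls) + 1}"),
                phenotype=kv.get("Name", kv.get("trait", "")),
                chromosome=str(chrom), ci_start=int(start), ci_end=int(end),
            ))
    return qtls


def write_qtl_gff3(qtls: list[QtlRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for q in qtls:
            attrs = f"ID={q.qtl_id};Name={q.phenotype}"
            fh.write(f"{q.chromosome}\tQTLdb\tQTL\t{q.ci_start}\t{q.ci_end}"
                     f"\t.\t.\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Overlap operations (sorted sweep per chromosome; desk-scale n)

def _by_chrom(items, chrom_of):
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(chrom_of(it), []).append(it)
    return out


def _classify_geometry(ev, gene: GeneRecord) -> str:
    if gene.tx_start >= ev.start_bp and gene.tx_end <= ev.end_bp:
        return "gene-within-cnv"
    if any(overlap_bp(ev.start_bp, ev.end_bp, s, e) > 0 for s, e in gene.exons):
        return "exon-overlap"
    if ev.start_bp >= gene.tx_start and ev.end_bp <= gene.tx_end:
        return "intron-contained"
    return "partial"


def overlap_genes(events, genes: list[GeneRecord]) -> pd.DataFrame:
    """Every (event, gene) pair sharing >= 1 bp, with geometry classified."""
    genes_by_chrom = _by_chrom(genes, lambda g: g.chromosome)
    ev_chroms = {e.chromosome for e in events}
    orphan = set(genes_by_chrom) - ev_chroms
    if orphan:
        log.warning("gene chromosomes absent from events, skipped: %s",
                    sorted(orphan))
    rows = []
    for ev in events:
        for g in sorted(genes_by_chrom.get(ev.chromosome, []),
                        key=lambda g: g.tx_start):
            ob = overlap_bp(ev.start_bp, ev.end_bp, g.tx_start, g.tx_end)
            if ob >= 1:
                rows.append((ev.name, g.symbol, "gene",
                             _classify_geometry(ev, g), ob,
                             ob / ev.length_bp))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def promoter_window(gene: GeneRecord, upstream_bp: int = 2000) -> tuple[int, int]:
    """Strand-aware upstream window, clipped at position 1."""
    if gene.strand == "+":
        return (max(1, gene.tss - upstream_bp), max(1, gene.tss - 1))
    return (gene.tss + 1, gene.tss + upstream_bp)


def overlap_promoters(events, genes: list[GeneRecord],
                      upstream_bp: int = 2000) -> pd.DataFrame:
    """Events intersecting the upstream promoter window of any gene."""
    genes_by_chrom = _by_chrom(genes, lambda g: g.chromosome)
    rows = []
    for ev in events:
        for g in sorted(genes_by_chrom.get(ev.chromosome, []),
                        key=lambda g: g.tx_start):
            ws, we = promoter_window(g, upstream_bp)
            if we < ws:
                continue  # TSS at the chromosome start, no window left
            ob = overlap_bp(ev.start_bp, ev.end_bp, ws, we)
            if ob >= 1:
                rows.append((ev.name, g.symbol, "promoter", "promoter",
                             ob, ob / ev.length_bp))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def overlap_qtls(events, qtls: list[QtlRecord], max_ci_bp: int = 30_000_000,
                 min_coverage: float = 0.5) -> pd.DataFrame:
    """QTL overlap: drop QTLs with CI span > max_ci_bp, then require a
    single QTL to cover >= min_coverage of the event's length."""
    kept = [q for q in qtls if q.ci_length <= max_ci_bp]
    n_dropped = len(qtls) - len(kept)
    if n_dropped:
        log.info("dropped %d QTLs with CI span > %d bp", n_dropped, max_ci_bp)
    qtls_by_chrom = _by_chrom(kept, lambda q: q.chromosome)
    rows = []
    for ev in events:
        for q in sorted(qtls_by_chrom.get(ev.chromosome, []),
                        key=lambda q: q.ci_start):
            ob = overlap_bp(ev.start_bp, ev.end_bp, q.ci_start, q.ci_end)
            cov = ob / ev.length_bp
            if ob >= 1 and cov >= min_coverage:
                rows.append((ev.name, q.qtl_id, "qtl", "covered", ob, cov))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
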