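"""Promoter corpus construction and I/O.

A promoter is the 400 bp immediately upstream of a gene's start codon on
the coding strand. Corpora are built from a genome FASTA plus gene
annotations (GFF3), split with a species holdout for testing, or
generated synthetically for fully self-contained pipelines.

Coordinate conventions: annotations are 1-based inclusive (GFF); every
internal offset is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGTN"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "GeneAnnotation",
    "Promoter",
    "PromoterCorpus",
    "extract_promoters",
    "split_corpus",
    "generate_synthetic_corpus",
    "read_genome_fasta",
    "read_gff_genes",
    "read_element_bed",
    "read_corpus_fasta",
    "write_corpus_fasta",
    "write_corpus_manifest",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene record; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def body(self) -> tuple[int, int]:
        """Gene body as a 0-based half-open interval."""
        return (self.start - 1, self.end)


@dataclass(frozen=True)
class Promoter:
    """An upstream regulatory window, oriented 5'→3' on the coding strand.

    ``tata_pos``/``tss_pos`` are optional 0-based offsets into ``sequence``.
    ``context5`` holds extra genomic sequence immediately 5' of the window
    (used to keep the 3' end anchored when training samples change length).
    """

    promoter_id: str
    species: str
    sequence: str
    tata_pos: int | None = None
    tss_pos: int | None = None
    context5: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"promoter {self.promoter_id}: invalid characters {sorted(bad)}")
        n = len(self.sequence)
        for name, pos in (("tata_pos", self.tata_pos), ("tss_pos", self.tss_pos)):
            if pos is not None and not (0 <= pos < n):
                raise ValueError(f"promoter {self.promoter_id}: {name}={pos} outside [0,{n})")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterCorpus:
    promoters: list[Promoter] = field(default_factory=list)
    split_label: str = "unsplit"

    def __post_init__(self):
        ids = [p.promoter_id for p in self.promoters]
        if len(ids) != len(set(ids)):
            raise ValueError("promoter_ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    def species_set(self) -> set[str]:
        return {p.species for p in self.promoters}

    def by_species(self) -> dict[str, list[Promoter]]:
        out: dict[str, list[Promoter]] = {}
        for p in self.promoters:
            out.setdefault(p.species, []).append(p)
        return out


# ----------------------------------------------------------------------
# Extraction
# ----------------------------------------------------------------------

def extract_promoters(
    genome: dict[str, str],
    annotations: list[GeneAnnotation],
    promoter_length: int = 400,
    min_separation: int = 100,
    species: str = "unknown",
    pad: int = 0,
    max_n_fraction: float = 0.10,
) -> PromoterCorpus:
    """Extract fixed-length promoters upstream of each gene's start codon.

    A gene is retained only when the window of ``promoter_length`` bases
    upstream of its start codon, extended a further ``min_separation``
    bases upstream, is free of every other annotated gene body, and the
    promoter window itself lies inside the contig. ``pad`` extra upstream
    bases (when available) are kept as 5' context for length-compensating
    sample generation.
    """
    for ann in annotations:
        if ann.contig not in genome:
            raise KeyError(f"gene {ann.gene_id}: contig {ann.contig!r} not in genome")
        clen = len(genome[ann.contig])
        if ann.end > clen:
            raise ValueError(f"gene {ann.gene_id}: end {ann.end} beyond contig length {clen}")

    bodies: dict[str, list[tuple[int, int, str]]] = {}
    for ann in annotations:
        s, e = ann.body
        bodies.setdefault(ann.contig, []).append((s, e, ann.gene_id))

    promoters: list[Promoter] = []
    for ann in annotations:
        contig_seq = genome[ann.contig].upper()
        clen = len(contig_seq)
        gs, ge = ann.body
        if ann.strand == "+":
            win = (gs - promoter_length, gs)
            margin = (win[0] - min_separation, gs)
        else:
            win = (ge, ge + promoter_length)
            margin = (ge, win[1] + min_separation)
        if win[0] < 0 or win[1] > clen:
            continue  # promoter window crosses the contig edge
        clash = any(
            other_id != ann.gene_id and s < margin[1] and e > margin[0]
            for s, e, other_id in bodies[ann.contig]
        )
        if clash:
            continue
        raw = contig_seq[win[0] : win[1]]
        if ann.strand == "+":
            seq = raw
            ctx = contig_seq[max(0, win[0] - pad) : win[0]]
        else:
            seq = reverse_complement(raw)
            ctx = reverse_complement(contig_seq[win[1] : min(clen, win[1] + pad)])
        if max_n_fraction is not None and seq.count("N") > max_n_fraction * len(seq):
            continue
        promoters.append(
            Promoter(promoter_id=ann.gene_id, species=species, sequence=seq, context5=ctx)
        )
    return PromoterCorpus(promoters=promoters, split_label="unsplit")


def split_corpus(
    corpus: PromoterCorpus,
    holdout_species: set[str],
    n_validation: int,
    seed: int,
) -> tuple[PromoterCorpus, PromoterCorpus, PromoterCorpus]:
    """Species-holdout split: holdout → test, seeded sample → validation, rest → train."""
    if not holdout_species & corpus.species_set():
        warnings.warn(f"holdout species {sorted(holdout_species)} absent from corpus; test set empty")
    test = [p for p in corpus if p.species in holdout_species]
    remainder = [p for p in corpus if p.species not in holdout_species]
    if n_validation >= len(remainder) and n_validation > 0:
        raise ValueError(f"n_validation={n_validation} >= {len(remainder)} non-holdout promoters")
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(len(remainder), size=n_validation, replace=False).tolist()) if n_validation else set()
    validation = [p for i, p in enumerate(remainder) if i in val_idx]
    train = [p for i, p in enumerate(remainder) if i not in val_idx]
    return (
        PromoterCorpus(train, "train"),
        PromoterCorpus(validation, "validation"),
        PromoterCorpus(test, "test"),
    )


# ----------------------------------------------------------------------
# Synthetic corpora
# ----------------------------------------------------------------------

def generate_synthetic_corpus(
    n_promoters: int,
    promoter_length: int = 400,
    gc_fraction: float = 0.5,
    plant_elements: bool = False,
    seed: int = 0,
    species: str = "synthetic",
    pad: int = 64,
) -> PromoterCorpus:
    """Generate i.i.d. random promoters, optionally with planted TATA/TSS.

    Base composition is symmetric within GC and AT. With
    ``plant_elements`` each promoter carries a TATAWAW motif (W ∈ {A,T})
    at a seeded position in the distal-to-mid region and a recorded TSS
    40–120 bp downstream of the motif. ``pad`` bases of random 5' context
    are attached for length-compensated sample generation.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    if promoter_length < 80:
        raise ValueError("promoter_length must be >= 80")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    bases = np.array(list("ACGT"))
    promoters = []
    for i in range(n_promoters):
        arr = rng.choice(bases, size=promoter_length + pad, p=probs)
        tata = tss = None
        if plant_elements:
            w1, w2 = rng.choice(["A", "T"], size=2)
            motif = f"TATA{w1}A{w2}"
            tata = int(rng.integers(promoter_length // 10, int(promoter_length * 0.6)))
            arr[pad + tata : pad + tata + len(motif)] = list(motif)
            tss = min(tata + int(rng.integers(40, 121)), promoter_length - 1)
        seq = "".join(arr[pad:])
        promoters.append(
            Promoter(
                promoter_id=f"{species}_{i:05d}",
                species=species,
                sequence=seq,
                tata_pos=tata,
                tss_pos=tss,
                context5="".join(arr[:pad]),
            )
        )
    return PromoterCorpus(promoters=promoters, split_label="unsplit")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff_genes(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file via gffutils (in-memory DB)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        out.append(GeneAnnotation(gene_id=gene_id, contig=feat.seqid, start=feat.start, end=feat.end, strand=feat.strand))
    return out


def read_element_bed(path) -> dict[str, dict[str, int]]:
    """Read TATA/TSS annotations from a BED-like file.

    Columns: promoter_id, start (0-based), end, element name (``tata`` or
    ``tss``). Returns {promoter_id: {"tata": pos, "tss": pos}}.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3])
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), {})[str(row.name).lower()] = int(row.start)
    return out


def annotate_corpus(corpus: PromoterCorpus, elements: dict[str, dict[str, int]]) -> PromoterCorpus:
    """Attach TATA/TSS offsets from a BED-derived mapping."""
    annotated = []
    for p in corpus:
        e = elements.get(p.promoter_id, {})
        annotated.append(replace(p, tata_pos=e.get("tata", p.tata_pos), tss_pos=e.get("tss", p.tss_pos)))
    return PromoterCorpus(annotated, corpus.split_label)


def write_corpus_fasta(corpus: PromoterCorpus, path) -> None:
    with open(path, "w") as fh:
        for p in corpus:
            tata = p.tata_pos if p.tata_pos is not None else "."
            tss = p.tss_pos if p.tss_pos is not None else "."
            ctx = f" context5={p.context5}" if p.context5 else ""
            fh.write(f">{p.promoter_id} species={p.species} tata={tata} tss={tss}{ctx}\n{p.sequence}\n")


def read_corpus_fasta(path, split_label: str = "unsplit") -> PromoterCorpus:
    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok)
        tata = meta.get("tata", ".")
        tss = meta.get("tss", ".")
        promoters.append(
            Promoter(
                promoter_id=rec.id,
                species=meta.get("species", "unknown"),
                sequence=str(rec.seq).upper(),
                tata_pos=None if tata == "." else int(tata),
                tss_pos=None if tss == "." else int(tss),
                context5=meta.get("context5", ""),
            )
        )
    return PromoterCorpus(promoters, split_label)


def write_corpus_manifest(corpus: PromoterCorpus, path) -> None:
    import pandas as pd

    rows = [
        {
            "promoter_id": p.promoter_id,
            "species": p.species,
            "length": p.length,
            "tata_pos": p.tata_pos,
            "tss_pos": p.tss_pos,
            "split": corpus.split_label,
        }
        for p in corpus
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
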