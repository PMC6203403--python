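"""Standard-format IO and haplotype reconstruction.

All internal coordinates are 0-based, half-open.  VCF (1-based, anchor-base
INDEL convention) and GFF3 (1-based, closed) are converted at the boundary.

Variant representation:

* SNP / complex substitution: ``ref_allele`` and ``alt_allele`` both
  non-empty; the haplotype replaces ``ref_allele`` at ``pos``.
* deletion: ``alt_allele == ""``; ``ref_allele`` is removed at ``pos``.
* insertion: ``ref_allele == ""``; ``alt_allele`` is inserted *before* the
  reference base at ``pos`` (i.e. it follows base ``pos - 1``).  Anchoring
  insertions to an explicit insertion point makes the "same position, same
  length" marker identity well defined.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """An in-memory reference: ordered chromosome names and uppercase sequences."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.sequences[name]
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name} contains non-ACGTN characters: {sorted(bad)}")

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class VariantCall:
    """One atomic or merged variant on reference coordinates for one sample."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample: str
    support: int | None = None
    het: bool = False

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("variant with empty ref and alt alleles")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")

    @property
    def end(self) -> int:
        """End of the consumed reference span (== pos for pure insertions)."""
        return self.pos + len(self.ref_allele)

    @property
    def is_insertion(self) -> bool:
        return not self.ref_allele

    @property
    def is_deletion(self) -> bool:
        return not self.alt_allele

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass
class SampleVariantSet:
    """Position-sorted variant calls of one (haploid / inbred) sample."""

    sample: str
    calls: dict[str, list[VariantCall]] = field(default_factory=dict)

    def add(self, call: VariantCall) -> None:
        self.calls.setdefault(call.chrom, []).append(call)

    def sort_and_validate(self, genome: ReferenceGenome | None = None) -> None:
        for chrom, calls in self.calls.items():
            calls.sort(key=lambda c: (c.pos, c.end))
            prev_end = -1
            prev = None
            for c in calls:
                if genome is not None:
                    ref = genome.sequences[c.chrom][c.pos : c.end]
                    if ref != c.ref_allele:
                        raise ValueError(
                            f"{self.sample} {chrom}:{c.pos} REF mismatch: "
                            f"call says {c.ref_allele!r}, genome has {ref!r}"
                        )
                # zero-length (insertion) spans may sit inside a deletion span;
                # two base-consuming calls must never overlap
                if c.ref_allele and prev is not None and c.pos < prev_end:
                    raise ValueError(
                        f"{self.sample} {chrom}: overlapping calls at {prev.pos} and {c.pos}"
                    )
                if c.ref_allele:
                    prev_end = c.end
                    prev = c

    def in_interval(self, chrom: str, start: int, end: int, chrom_len: int) -> list[VariantCall]:
        """Calls owned by [start, end): leftmost reference base inside, or an
        insertion point inside (an end-of-chromosome insertion belongs to the
        final window)."""
        out = []
        for c in self.calls.get(chrom, []):
            if c.is_insertion:
                if start <= c.pos < end or (c.pos == end == chrom_len):
                    out.append(c)
            elif start <= c.pos < end:
                out.append(c)
        return out


@dataclass
class GeneModel:
    """One protein-coding gene model (single representative transcript)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_id}: overlapping intervals")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Read a multi-record FASTA, uppercasing sequences."""
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if not names:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(names, seqs)


def write_reference(path: str | os.PathLike, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _strip_anchor(pos1: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Convert a VCF record (1-based pos, anchor-base alleles) to the internal
    anchor-free representation with a 0-based position."""
    pos = pos1 - 1
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_sample_vcf(
    path: str | os.PathLike,
    sample: str,
    genome: ReferenceGenome | None = None,
) -> SampleVariantSet:
    """Read one sample's (haploid) variant calls from a VCF file.

    Anchor bases are stripped so that ref and alt share no common prefix; a
    stripped-empty ref makes an insertion anchored before the remaining
    position.  ``support`` is taken from INFO/DP when present, heterozygosity
    from the first genotype column.
    """
    import pysam

    varset = SampleVariantSet(sample)
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            pos, ref, alt = _strip_anchor(rec.pos, rec.ref, alt)
            try:
                support = rec.info["DP"]
            except (KeyError, ValueError):
                support = None
            if isinstance(support, tuple):
                support = support[0]
            het = False
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and len([a for a in gt if a is not None]) > 1:
                    het = len({a for a in gt if a is not None}) > 1
            varset.add(
                VariantCall(rec.chrom, pos, ref, alt, sample, support=support, het=het)
            )
    varset.sort_and_validate(genome)
    return varset


def read_gff3(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read gene models (gene -> first mRNA -> exon/CDS) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            transcript_id=mrna.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=sorted(exons),
            cds=sorted(cds),
        )
    return models


def write_gff3(path: str | os.PathLike, models: dict[str, GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models.values():
            s, e = gm.start + 1, gm.end
            fh.write(
                f"{gm.chrom}\tvarsync\tgene\t{s}\t{e}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            fh.write(
                f"{gm.chrom}\tvarsync\tmRNA\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID={gm.transcript_id};Parent={gm.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(gm.exons):
                fh.write(
                    f"{gm.chrom}\tvarsync\texon\t{xs + 1}\t{xe}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.transcript_id}.exon{i};Parent={gm.transcript_id}\n"
                )
            for i, (cs, ce) in enumerate(gm.cds):
                fh.write(
                    f"{gm.chrom}\tvarsync\tCDS\t{cs + 1}\t{ce}\t.\t{gm.strand}\t0\t"
                    f"ID={gm.transcript_id}.cds{i};Parent={gm.transcript_id}\n"
                )


def read_phenotypes(path: str | os.PathLike) -> pd.Series:
    """Read a two-column TSV (sample id, phenotype value) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    return pd.Series(df[1].astype(float).values, index=df[0].values, name="phenotype")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------


def _to_vcf_alleles(genome: ReferenceGenome, chrom: str, pos: int, ref: str, alt: str):
    """Internal anchor-free representation -> (1-based pos, REF, ALT)."""
    seq = genome.sequences[chrom]
    if ref and alt:
        return pos + 1, ref, alt
    if not alt:  # deletion: anchor on the preceding base (or following at pos 0)
        if pos > 0:
            anchor = seq[pos - 1]
            return pos, anchor + ref, anchor
        anchor = seq[pos + len(ref)]
        return 1, ref + anchor, anchor
    # insertion before base `pos`: anchor on the base it follows
    if pos > 0:
        anchor = seq[pos - 1]
        return pos, anchor, anchor + alt
    anchor = seq[0]
    return 1, anchor, alt + anchor


def _vcf_header(genome: ReferenceGenome, samples: list[str]):
    import pysam

    hdr = pysam.VariantHeader()
    for name in genome.chrom_names:
        hdr.contigs.add(name, length=genome.length(name))
    hdr.info.add("DP", 1, "Integer", "Read support for the call")
    hdr.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        hdr.add_sample(s)
    return hdr


def write_sample_vcf(
    path: str | os.PathLike, genome: ReferenceGenome, varset: SampleVariantSet
) -> None:
    """Write one sample's calls as a single-sample VCF (GT=1 throughout)."""
    import pysam

    hdr = _vcf_header(genome, [varset.sample])
    with pysam.VariantFile(str(path), "w", header=hdr) as vcf:
        for chrom in genome.chrom_names:
            for c in sorted(varset.calls.get(chrom, []), key=lambda c: (c.pos, c.end)):
                pos1, ref, alt = _to_vcf_alleles(genome, chrom, c.pos, c.ref_allele, c.alt_allele)
                rec = vcf.new_record(contig=chrom, start=pos1 - 1, alleles=(ref, alt))
                if c.support is not None:
                    rec.info["DP"] = int(c.support)
                rec.samples[varset.sample]["GT"] = (0, 1) if c.het else (1,)
                vcf.write(rec)


def write_multisample_vcf(path, genome, markers, genotypes, samples) -> None:
    """Write the synchronized population table as a multi-sample VCF.

    ``markers`` is the synchronizer's marker DataFrame; ``genotypes`` a
    samples x markers array in {0, 1} (-1 for missing).
    """
    import pysam

    hdr = _vcf_header(genome, list(samples))
    with pysam.VariantFile(str(path), "w", header=hdr) as vcf:
        for mi, m in markers.iterrows():
            if m.kind == "ins":
                ref_allele, alt_allele = "", m.alt
            elif m.kind == "del":
                ref_allele, alt_allele = m.ref, ""
            else:
                ref_allele, alt_allele = m.ref, m.alt
            pos1, ref, alt = _to_vcf_alleles(genome, m.chrom, int(m.pos), ref_allele, alt_allele)
            rec = vcf.new_record(contig=m.chrom, start=pos1 - 1, alleles=(ref, alt))
            for si, s in enumerate(samples):
                g = int(genotypes[si, mi])
                rec.samples[s]["GT"] = (None,) if g < 0 else (g,)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# haplotype reconstruction
# ---------------------------------------------------------------------------


@dataclass
class CoordinateMap:
    """Monotone map between a reference interval and its edited haplotype.

    ``ref2hap[i]`` gives, for reference offset ``start + i`` (including the
    closing boundary ``end``), the corresponding haplotype offset.  A deleted
    reference base maps to the haplotype offset of the deletion's left edge;
    ``present[i]`` is False for such bases.  ``hap2ref[j]`` holds the
    reference offset of haplotype base ``j``, or -1 for inserted bases.
    """

    chrom: str
    start: int
    end: int
    ref2hap: np.ndarray
    present: np.ndarray
    hap2ref: np.ndarray

    def to_hap(self, ref_pos: int) -> int:
        return int(self.ref2hap[ref_pos - self.start])

    def is_present(self, ref_pos: int) -> bool:
        return bool(self.present[ref_pos - self.start])

    def to_ref(self, hap_pos: int) -> int:
        return int(self.hap2ref[hap_pos])


def apply_variants(
    genome: ReferenceGenome,
    varset: SampleVariantSet,
    chrom: str,
    start: int,
    end: int,
) -> tuple[str, CoordinateMap]:
    """Edit the reference slice [start, end) with the sample's calls.

    Calls are owned by the interval containing their leftmost reference base
    (insertions: their insertion point).  A deletion straddling ``end``
    extends the effective interval so the full allele is applied.
    """
    ref_seq = genome.sequences[chrom]
    chrom_len = len(ref_seq)
    calls = varset.in_interval(chrom, start, end, chrom_len)
    eff_end = end
    for c in calls:
        eff_end = max(eff_end, c.end)
    if eff_end > chrom_len:
        raise ValueError(f"variant extends past chromosome end ({eff_end} > {chrom_len})")

    n_ref = eff_end - start
    ref2hap = np.zeros(n_ref + 1, dtype=np.int64)
    present = np.ones(n_ref + 1, dtype=bool)
    parts: list[str] = []
    hap2ref_parts: list[np.ndarray] = []
    cursor = start  # next unemitted reference position
    hap_len = 0

    def emit_ref(upto: int) -> None:
        nonlocal cursor, hap_len
        if upto > cursor:
            seg = ref_seq[cursor:upto]
            parts.append(seg)
            idx = np.arange(cursor - start, upto - start)
            ref2hap[idx] = hap_len + np.arange(len(seg))
            hap2ref_parts.append(np.arange(cursor, upto))
            hap_len += len(seg)
            cursor = upto

    def emit_alt(alt: str) -> None:
        nonlocal hap_len
        if alt:
            parts.append(alt)
            hap2ref_parts.append(np.full(len(alt), -1, dtype=np.int64))
            hap_len += len(alt)

    # insertions sort before substitutions at the same coordinate: the
    # insertion precedes the (possibly replaced) base at `pos`
    for c in sorted(calls, key=lambda c: (c.pos, bool(c.ref_allele))):
        if c.is_insertion and c.pos < cursor:
            # insertion point inside an already-applied deletion span:
            # overlapping INDELs are independent records; the inserted text
            # lands at the deletion's edit site
            emit_alt(c.alt_allele)
            continue
        if c.pos < cursor:
            raise ValueError(f"{varset.sample} {chrom}: overlapping calls at {c.pos}")
        emit_ref(c.pos)
        if c.ref_allele and ref_seq[c.pos : c.end] != c.ref_allele:
            raise ValueError(
                f"{varset.sample} {chrom}:{c.pos} REF mismatch "
                f"({c.ref_allele!r} vs {ref_seq[c.pos:c.end]!r})"
            )
        left_edge = hap_len
        emit_alt(c.alt_allele)
        if c.ref_allele:
            idx = np.arange(c.pos - start, c.end - start)
            if c.is_deletion:
                ref2hap[idx] = left_edge
                present[idx] = False
            else:
                # substitution: consumed bases map onto the replacing text
                # (clamped to its length)
                ref2hap[idx] = left_edge + np.minimum(
                    np.arange(len(idx)), max(len(c.alt_allele) - 1, 0)
                )
                present[idx] = len(c.alt_allele) > 0
            cursor = c.end
    emit_ref(eff_end)
    ref2hap[n_ref] = hap_len
    hap = "".join(parts)
    hap2ref = (
        np.concatenate(hap2ref_parts) if hap2ref_parts else np.empty(0, dtype=np.int64)
    )
    cmap = CoordinateMap(chrom, start, eff_end, ref2hap, present, hap2ref)
    return hap, cmap
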