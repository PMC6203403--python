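"""Per-gene, per-sample open reading frame state (ORFS) annotation.

A gene's ORFS on a sample haplotype is *conserved* when at least one of three
annotation routes yields a gene model passing all of four criteria, and
*interrupted* when every evaluable route violates at least one:

1. start codon (ATG) and stop codon (TAA/TAG/TGA) intact;
2. every splice site pair equals the reference pair, or follows the GT-AG
   rule, or belongs to the minor-class whitelist
   {GC-AG, GG-AG, GT-TG, GT-CG, CT-AG};
3. no premature stop codon;
4. spliced CDS length divisible by 3.

The three routes are (a) spliced alignment of the reference CDS to the
haplotype, (b) codon-level spliced alignment of the reference protein, and
(c) direct coordinate lift-over of the reference model.  Evaluating the
routes jointly is deliberately conservative: an alternative gene model that
restores protein coding rescues the gene, so single variants are never
judged in isolation.

The built-in spliced aligner is an est2genome-style dynamic programme with
an intron state (entry penalty -10, minimum intron length 10), match +5 /
mismatch -4 and affine gaps, run over the gene haplotype (gene span plus
1 kb flanks); a route whose best alignment scores below 10 is unevaluable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from varsync.core_io import (
    CoordinateMap,
    GeneModel,
    ReferenceGenome,
    SampleVariantSet,
    apply_variants,
    revcomp,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
SPLICE_WHITELIST = {("GC", "AG"), ("GG", "AG"), ("GT", "TG"), ("GT", "CG"), ("CT", "AG")}
CANONICAL_SPLICE = ("GT", "AG")

MATCH = 5.0
MISMATCH = -4.0
GAP_OPEN = -12.0
GAP_EXT = -4.0
INTRON_PENALTY = -10.0
FRAMESHIFT_PENALTY = -28.0  # codon-level route: consuming 1/2/4/5 bases per residue
# extended splice-site consensus beyond GT..AG; deviations are penalised per
# base so introns snap to real splice sites rather than arbitrary dinucleotides
DONOR_CONTEXT = "AAG"  # intron positions +3..+5 (after GT)
ACCEPTOR_CONTEXT = "TTC"  # intron positions -5..-3 (before AG)
CONTEXT_MISMATCH = -8.0
MIN_INTRON = 10
MAX_INTRON = 30_000
MIN_SCORE = 10.0

CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        CODON_TABLE[stop] = "*"


_build_codon_table()


def translate(seq: str) -> str:
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# gene haplotypes
# ---------------------------------------------------------------------------


@dataclass
class GeneHaplotype:
    """The gene span +/- flank on one sample's haplotype, oriented 5'->3'."""

    gene_id: str
    sample: str
    chrom: str
    strand: str
    seq: str
    flank_start: int  # reference start of the extracted (plus-strand) span
    flank_end: int
    cmap: CoordinateMap  # plus-strand reference -> haplotype map

    def __len__(self) -> int:
        return len(self.seq)

    def local_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a reference half-open interval to oriented local coordinates."""
        ls = int(self.cmap.ref2hap[start - self.flank_start])
        le = int(self.cmap.ref2hap[end - self.flank_start])
        if self.strand == "-":
            n = len(self.seq)
            return n - le, n - ls
        return ls, le


def extract_gene_haplotype(
    genome: ReferenceGenome,
    varset: SampleVariantSet,
    model: GeneModel,
    flank: int = 1000,
) -> GeneHaplotype:
    """Reconstruct the gene region (+-flank) on the sample haplotype; minus
    strand genes are returned reverse-complemented."""
    chrom_len = genome.length(model.chrom)
    fs = model.start - flank
    fe = model.end + flank
    if fs < 0 or fe > chrom_len:
        warnings.warn(
            f"{model.gene_id}: flanked span clipped to chromosome bounds", stacklevel=2
        )
        fs = max(fs, 0)
        fe = min(fe, chrom_len)
    hap, cmap = apply_variants(genome, varset, model.chrom, fs, fe)
    seq = revcomp(hap) if model.strand == "-" else hap
    return GeneHaplotype(
        model.gene_id, varset.sample, model.chrom, model.strand, seq, fs, cmap.end, cmap
    )


# ---------------------------------------------------------------------------
# candidate annotations
# ---------------------------------------------------------------------------


@dataclass
class CandidateAnnotation:
    """One route's gene model on gene-haplotype (oriented local) coordinates."""

    route: str  # liftover | cds_align | protein_align
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    score: float | None = None
    n_frameshifts: int = 0  # explicit frameshift operations in the alignment

    def spliced_cds(self, seq: str) -> str:
        return "".join(seq[s:e] for s, e in self.cds)


def reference_gene_data(genome: ReferenceGenome, model: GeneModel):
    """Oriented reference CDS / protein / splice pairs for a gene model."""
    seq = genome.sequences[model.chrom]
    if model.strand == "-":
        cds_parts = [revcomp(seq[s:e]) for s, e in reversed(model.cds)]
        pairs = []
        for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
            # oriented donor/acceptor for a minus-strand intron (e1, s2)
            donor = revcomp(seq[s2 - 2 : s2])
            acceptor = revcomp(seq[e1 : e1 + 2])
            pairs.append((donor, acceptor))
        pairs.reverse()
    else:
        cds_parts = [seq[s:e] for s, e in model.cds]
        pairs = [
            (seq[e1 : e1 + 2], seq[s2 - 2 : s2])
            for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:])
        ]
    cds_seq = "".join(cds_parts)
    protein = translate(cds_seq[:-3]) if len(cds_seq) >= 6 else ""
    return cds_seq, protein, pairs


def annotate_by_liftover(hap: GeneHaplotype, model: GeneModel) -> CandidateAnnotation:
    """Map every reference exon/CDS boundary through the coordinate map.

    A boundary inside a deletion lands on the deletion's left haplotype edge;
    intervals deleted entirely vanish.
    """
    exons = []
    for s, e in model.exons:
        ls, le = hap.local_interval(s, e)
        if le > ls:
            exons.append((ls, le))
    cds = []
    for s, e in model.cds:
        ls, le = hap.local_interval(s, e)
        if le > ls:
            cds.append((ls, le))
    return CandidateAnnotation("liftover", sorted(exons), sorted(cds))


# ---------------------------------------------------------------------------
# spliced-alignment dynamic programme
# ---------------------------------------------------------------------------

_NEG = -1e18


def _splice_site_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Donor/acceptor admissibility (GT / AG) and extended-context penalties."""
    n = len(seq)
    donor_ok = np.zeros(n + 1, dtype=bool)
    acceptor_ok = np.zeros(n + 1, dtype=bool)
    donor_pen = np.zeros(n + 1)
    acceptor_pen = np.zeros(n + 1)
    for j in range(n - 1):
        if seq[j : j + 2] == "GT":
            donor_ok[j] = True
            ctx = seq[j + 2 : j + 2 + len(DONOR_CONTEXT)]
            donor_pen[j] = CONTEXT_MISMATCH * sum(
                1 for a, b in zip(ctx.ljust(len(DONOR_CONTEXT), "N"), DONOR_CONTEXT) if a != b
            )
    for j in range(2, n + 1):
        if seq[j - 2 : j] == "AG":
            acceptor_ok[j] = True
            lo = max(j - 2 - len(ACCEPTOR_CONTEXT), 0)
            ctx = seq[lo : j - 2].rjust(len(ACCEPTOR_CONTEXT), "N")
            acceptor_pen[j] = CONTEXT_MISMATCH * sum(
                1 for a, b in zip(ctx, ACCEPTOR_CONTEXT) if a != b
            )
    return donor_ok, acceptor_ok, donor_pen, acceptor_pen


def _fit_spliced_dp(
    score_rows: np.ndarray,
    step: int,
    donor_ok: np.ndarray | None = None,
    acceptor_ok: np.ndarray | None = None,
    donor_pen: np.ndarray | None = None,
    acceptor_pen: np.ndarray | None = None,
):
    """Fit alignment of a query (rows) to a genome (columns) with intron jumps.

    ``score_rows[i, j]`` scores aligning query unit ``i`` so that it consumes
    genome ``[j-step, j)``.  The query must be consumed globally; genome
    prefix and suffix are free.  Introns may only open at canonical GT donors
    and close at AG acceptors (``donor_ok`` / ``acceptor_ok`` masks); this is
    how est2genome-class aligners model splice sites, and it stops frame
    shifts from being absorbed by sliding an intron boundary onto an
    arbitrary dinucleotide.  Returns (score, M, X) for traceback, where M is
    the match-state matrix and X the trailing query-gap state.
    """
    m, n1 = score_rows.shape
    if donor_ok is None:
        donor_ok = np.ones(n1, dtype=bool)
    if acceptor_ok is None:
        acceptor_ok = np.ones(n1, dtype=bool)
    if donor_pen is None:
        donor_pen = np.zeros(n1)
    if acceptor_pen is None:
        acceptor_pen = np.zeros(n1)
    allow_frameshift = step == 3
    M = np.full((m + 1, n1), _NEG)
    X = np.full((m + 1, n1), _NEG)
    M[0] = 0.0
    for i in range(1, m + 1):
        prev_m = M[i - 1]
        base_fs = np.maximum(prev_m, X[i - 1])  # frameshift may not follow an intron
        prev_best = base_fs.copy()
        # intron arrival (length >= MIN_INTRON, entry penalty, GT..AG only,
        # consensus-context scored)
        if n1 > MIN_INTRON:
            acc = np.maximum.accumulate(np.where(donor_ok, prev_m + donor_pen, _NEG))
            arrival = np.full(n1, _NEG)
            arrival[MIN_INTRON:] = np.where(
                acceptor_ok[MIN_INTRON:],
                acc[: n1 - MIN_INTRON] + INTRON_PENALTY + acceptor_pen[MIN_INTRON:],
                _NEG,
            )
            prev_best = np.maximum(prev_best, arrival)
        # short genome gap (insertion in the haplotype within an exon)
        for p in range(step):
            idx = np.arange(p, n1, step)
            if len(idx) < 2:
                continue
            k = np.arange(len(idx), dtype=float)
            acc = np.maximum.accumulate(prev_m[idx] - GAP_EXT * k)
            gap = GAP_OPEN + GAP_EXT * (k[1:] - 1.0) + acc[:-1]
            prev_best[idx[1:]] = np.maximum(prev_best[idx[1:]], gap)
        Mi = np.full(n1, _NEG)
        Mi[step:] = prev_best[:-step] + score_rows[i - 1, step:]
        if allow_frameshift:
            for c in (1, 2, 4, 5):
                if n1 > c:
                    cand = np.full(n1, _NEG)
                    cand[c:] = base_fs[:-c] + score_rows[i - 1, c:] + FRAMESHIFT_PENALTY
                    np.maximum(Mi, cand, out=Mi)
        M[i] = Mi
        X[i] = np.maximum(X[i - 1] + GAP_EXT, prev_m + GAP_OPEN)
    final = np.maximum(M[m], X[m])
    return float(final.max()), M, X


def _arrival_parts(
    prev_m: np.ndarray,
    step: int,
    j: int,
    donor_ok: np.ndarray,
    acceptor_ok: np.ndarray,
    donor_pen: np.ndarray,
    acceptor_pen: np.ndarray,
):
    """Best intron / genome-gap arrival values (with origins) at column j."""
    intron_val, intron_from = _NEG, -1
    if j >= MIN_INTRON and acceptor_ok[j]:
        masked = np.where(
            donor_ok[: j - MIN_INTRON + 1],
            (prev_m + donor_pen)[: j - MIN_INTRON + 1],
            _NEG,
        )
        k = int(np.argmax(masked))
        if masked[k] > _NEG / 2:
            intron_val = float(masked[k]) + INTRON_PENALTY + float(acceptor_pen[j])
            intron_from = k
    gap_val, gap_from = _NEG, -1
    k = j - step
    t = 1
    while k >= 0:
        v = float(prev_m[k]) + GAP_OPEN + GAP_EXT * (t - 1)
        if v > gap_val:
            gap_val, gap_from = v, k
        k -= step
        t += 1
    return intron_val, intron_from, gap_val, gap_from


def _traceback(
    M: np.ndarray,
    X: np.ndarray,
    score_rows: np.ndarray,
    step: int,
    donor_ok: np.ndarray,
    acceptor_ok: np.ndarray,
    donor_pen: np.ndarray,
    acceptor_pen: np.ndarray,
):
    """Recover consumed genome blocks (exons) from the DP matrices."""
    m = score_rows.shape[0]
    final = np.maximum(M[m], X[m])
    j = int(np.argmax(final))
    i = m
    state = "M" if M[m, j] >= X[m, j] else "X"
    segments: list[tuple[int, int]] = []
    n_frameshifts = 0
    eps = 1e-6
    while i > 0:
        if state == "X":
            if X[i, j] <= _NEG / 2:
                break
            if abs(X[i, j] - (X[i - 1, j] + GAP_EXT)) < eps:
                i -= 1
            else:
                i -= 1
                state = "M"
        else:
            if M[i, j] <= _NEG / 2:
                break
            pb = j - step
            target = M[i, j] - score_rows[i - 1, j]
            i -= 1
            if pb >= 0 and abs(M[i, pb] - target) < eps:
                segments.append((pb, j))
                j = pb
                continue
            if pb >= 0 and abs(X[i, pb] - target) < eps:
                segments.append((pb, j))
                j = pb
                state = "X"
                continue
            done = False
            if step == 3:  # frameshift transitions of the codon-level route
                for c in (1, 2, 4, 5):
                    jc = j - c
                    if jc < 0:
                        continue
                    if abs(M[i, jc] + FRAMESHIFT_PENALTY - target) < eps:
                        segments.append((jc, j))
                        n_frameshifts += 1
                        j = jc
                        done = True
                        break
                    if abs(X[i, jc] + FRAMESHIFT_PENALTY - target) < eps:
                        segments.append((jc, j))
                        n_frameshifts += 1
                        j = jc
                        state = "X"
                        done = True
                        break
            if done:
                continue
            intron_val, intron_from, gap_val, gap_from = _arrival_parts(
                M[i], step, pb, donor_ok, acceptor_ok, donor_pen, acceptor_pen
            )
            if abs(intron_val - target) < eps:
                segments.append((pb, j))
                j = intron_from  # intron spans [intron_from, pb)
            elif abs(gap_val - target) < eps:
                segments.append((pb, j))
                segments.append((gap_from, pb))  # haplotype insertion inside exon
                j = gap_from
            else:  # pragma: no cover - numerical fallback
                segments.append((pb, j))
                j = pb
    segments.sort()
    exons: list[tuple[int, int]] = []
    for s, e in segments:
        if exons and s <= exons[-1][1]:
            exons[-1] = (exons[-1][0], max(exons[-1][1], e))
        else:
            exons.append((s, e))
    return exons, n_frameshifts


def annotate_by_spliced_alignment(
    hap: GeneHaplotype | str,
    query: str,
    mode: str = "cds",
) -> CandidateAnnotation | None:
    """Best spliced alignment of the reference CDS (``mode='cds'``) or protein
    (``mode='protein'``, codon steps) to the gene haplotype.  Returns None
    (route unevaluable) when the best score falls below the minimum."""
    seq = hap if isinstance(hap, str) else hap.seq
    n = len(seq)
    if not query or n == 0:
        return None
    g = np.frombuffer(seq.encode(), dtype=np.uint8)
    if mode == "cds":
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        m = len(q)
        score_rows = np.full((m, n + 1), _NEG)
        eq = q[:, None] == g[None, :]
        valid = (q[:, None] != ord("N")) & (g[None, :] != ord("N"))  # N never matches
        score_rows[:, 1:] = np.where(eq & valid, MATCH, MISMATCH)
        step = 1
    elif mode == "protein":
        m = len(query)
        if n < 3:
            return None
        codons = np.array([CODON_TABLE.get(seq[j - 3 : j], "X") for j in range(3, n + 1)])
        score_rows = np.full((m, n + 1), _NEG)
        qarr = np.array(list(query))
        eq = qarr[:, None] == codons[None, :]
        score_rows[:, 3:] = np.where(eq, MATCH, MISMATCH)
        step = 3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    donor_ok, acceptor_ok, donor_pen, acceptor_pen = _splice_site_arrays(seq)
    score, M, X = _fit_spliced_dp(
        score_rows, step, donor_ok, acceptor_ok, donor_pen, acceptor_pen
    )
    if score < MIN_SCORE:
        return None
    exons, n_fs = _traceback(
        M, X, score_rows, step, donor_ok, acceptor_ok, donor_pen, acceptor_pen
    )
    if not exons:
        return None
    if mode == "protein":
        # the protein query lacks the stop codon; extend to cover it
        s, e = exons[-1]
        exons[-1] = (s, min(e + 3, n))
    route = "cds_align" if mode == "cds" else "protein_align"
    return CandidateAnnotation(route, exons, list(exons), score=score, n_frameshifts=n_fs)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def evaluate_criteria(
    ann: CandidateAnnotation,
    hap: GeneHaplotype | str,
    ref_pairs: list[tuple[str, str]],
) -> dict[str, bool] | None:
    """The four ORFS criteria for one candidate annotation.

    Splice pairs are checked on the coding strand: a pair is intact when it
    equals the reference pair at the same intron index, follows GT-AG, or
    belongs to the minor-class whitelist.
    """
    seq = hap if isinstance(hap, str) else hap.seq
    if not ann.cds:
        return None
    cds_seq = ann.spliced_cds(seq)
    if len(cds_seq) < 3:
        return None
    flags = {}
    flags["start_stop_intact"] = cds_seq[:3] == "ATG" and cds_seq[-3:] in STOP_CODONS
    # an alignment that needed explicit frameshift operations has no intact
    # reading frame, whatever the summed exon length happens to be
    flags["frame_ok"] = len(cds_seq) % 3 == 0 and ann.n_frameshifts == 0
    premature = False
    for i in range(0, len(cds_seq) - 3, 3):
        if cds_seq[i : i + 3] in STOP_CODONS:
            premature = True
            break
    flags["no_premature_stop"] = not premature
    splice_ok = True
    for k, ((s1, e1), (s2, e2)) in enumerate(zip(ann.exons, ann.exons[1:])):
        pair = (seq[e1 : e1 + 2], seq[s2 - 2 : s2])
        if pair == CANONICAL_SPLICE or pair in SPLICE_WHITELIST:
            continue
        if k < len(ref_pairs) and pair == ref_pairs[k]:
            continue
        splice_ok = False
        break
    flags["splice_intact"] = splice_ok
    return flags


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------


@dataclass
class OrfsCall:
    """Per gene x sample verdict with per-route criterion diagnostics."""

    gene_id: str
    sample: str
    state: str  # conserved | interrupted | missing
    route_flags: dict[str, dict[str, bool] | None] = field(default_factory=dict)
    trustable: bool = True


def call_orfs(
    gene_id: str,
    sample: str,
    route_flags: dict[str, dict[str, bool] | None],
) -> OrfsCall:
    """Conservative combination: interrupted only if *every* evaluable route
    violates at least one criterion; missing if no route is evaluable."""
    evaluated = {r: f for r, f in route_flags.items() if f is not None}
    if not evaluated:
        state = "missing"
    elif all(not all(f.values()) for f in evaluated.values()):
        state = "interrupted"
    else:
        state = "conserved"
    return OrfsCall(gene_id, sample, state, route_flags)


def flag_trustable(
    call: OrfsCall,
    model: GeneModel,
    coverage: np.ndarray | None = None,
    indel_confirmed: dict[tuple, bool] | None = None,
    varset: SampleVariantSet | None = None,
) -> bool:
    """An ORFS call is trustable when every CDS base has coverage >= 1 and all
    CDS INDELs are confirmed by both assembly routes.  Absent quality inputs
    default to trustable so the pipeline runs without read data."""
    if coverage is not None:
        for s, e in model.cds:
            if np.any(coverage[s:e] < 1):
                return False
    if indel_confirmed is not None and varset is not None:
        for c in varset.calls.get(model.chrom, []):
            if not c.is_indel:
                continue
            inside = any((c.pos < e and max(c.end, c.pos + 1) > s) for s, e in model.cds)
            if inside and not indel_confirmed.get(
                (c.chrom, c.pos, c.ref_allele, c.alt_allele), False
            ):
                return False
    return True


def annotate_gene_sample(
    genome: ReferenceGenome,
    varset: SampleVariantSet,
    model: GeneModel,
    flank: int = 1000,
    ref_data=None,
    ref_flags: dict[str, dict[str, bool] | None] | None = None,
    ref_region: str | None = None,
) -> OrfsCall:
    """Run the three annotation routes for one gene x sample and combine."""
    if ref_data is None:
        ref_data = reference_gene_data(genome, model)
    cds_seq, protein, ref_pairs = ref_data
    hap = extract_gene_haplotype(genome, varset, model, flank=flank)
    if ref_region is not None and hap.seq == ref_region and ref_flags is not None:
        return call_orfs(model.gene_id, varset.sample, dict(ref_flags))
    route_flags: dict[str, dict[str, bool] | None] = {}
    lift = annotate_by_liftover(hap, model)
    route_flags["liftover"] = evaluate_criteria(lift, hap, ref_pairs)
    cds_ann = annotate_by_spliced_alignment(hap, cds_seq, mode="cds")
    route_flags["cds_align"] = evaluate_criteria(cds_ann, hap, ref_pairs) if cds_ann else None
    prot_ann = annotate_by_spliced_alignment(hap, protein, mode="protein")
    route_flags["protein_align"] = (
        evaluate_criteria(prot_ann, hap, ref_pairs) if prot_ann else None
    )
    return call_orfs(model.gene_id, varset.sample, route_flags)


def annotate_population(
    genome: ReferenceGenome,
    varsets: list[SampleVariantSet],
    models: dict[str, GeneModel],
    flank: int = 1000,
    alt_reference: dict[str, str] | None = None,
):
    """ORFS matrix for all genes x samples.

    Returns a DataFrame (rows genes, columns samples; 0 = conserved,
    1 = interrupted, NaN = missing) plus the full OrfsCall objects.

    ``alt_reference`` maps gene ids to the sample whose haplotype supplies
    the query CDS/protein when the reference copy of that gene is itself
    non-functional.
    """
    import pandas as pd

    alt_reference = alt_reference or {}
    varsets_by_sample = {vs.sample: vs for vs in varsets}
    samples = [vs.sample for vs in varsets]
    values = np.full((len(models), len(samples)), np.nan)
    calls: dict[tuple[str, str], OrfsCall] = {}
    gene_ids = list(models)
    for gi, gene_id in enumerate(gene_ids):
        model = models[gene_id]
        ref_data = reference_gene_data(genome, model)
        if gene_id in alt_reference:
            alt_vs = varsets_by_sample[alt_reference[gene_id]]
            alt_hap = extract_gene_haplotype(genome, alt_vs, model, flank=flank)
            alt_lift = annotate_by_liftover(alt_hap, model)
            alt_cds = alt_lift.spliced_cds(alt_hap.seq)
            alt_prot = translate(alt_cds[:-3]) if len(alt_cds) >= 6 else ""
            alt_pairs = [
                (alt_hap.seq[e1 : e1 + 2], alt_hap.seq[s2 - 2 : s2])
                for (s1, e1), (s2, e2) in zip(alt_lift.exons, alt_lift.exons[1:])
            ]
            ref_data = (alt_cds, alt_prot, alt_pairs)
        fs = max(model.start - flank, 0)
        fe = min(model.end + flank, genome.length(model.chrom))
        region = genome.sequences[model.chrom][fs:fe]
        ref_region = revcomp(region) if model.strand == "-" else region
        empty = SampleVariantSet("__ref__")
        ref_call = annotate_gene_sample(genome, empty, model, flank=flank, ref_data=ref_data)
        for si, vs in enumerate(varsets):
            call = annotate_gene_sample(
                genome, vs, model, flank=flank, ref_data=ref_data,
                ref_flags=ref_call.route_flags, ref_region=ref_region,
            )
            calls[(gene_id, vs.sample)] = call
            if call.state == "conserved":
                values[gi, si] = 0.0
            elif call.state == "interrupted":
                values[gi, si] = 1.0
    matrix = pd.DataFrame(values, index=gene_ids, columns=samples)
    return matrix, calls
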