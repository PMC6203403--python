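"""Synthetic data generation: genomes, gene models, isomorph-bearing
populations, phenotypes with known architecture, and the loss-of-function
power simulation.

The generators emulate the study conditions the pipeline targets: an inbred
(haploid-equivalent) population whose shared underlying INDELs reach the
caller as different but sequence-equivalent representations (alignment
isomorphs), genes carrying independent ORF-shifting mutations, and
phenotypes with additive genetic effects plus a polygenic background.
Every generator is driven by a ``numpy.random.Generator`` so a seed fully
determines all outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from varsync.core_io import (
    GeneModel,
    ReferenceGenome,
    SampleVariantSet,
    VariantCall,
    apply_variants,
    revcomp,
)
from varsync.synchronizer import make_windows

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in _STOPS and "".join(c) != "ATG"
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; the seed determines every output."""

    seed: int = 0
    n_samples: int = 20
    chrom_length: int = 200_000
    n_genes: int = 8
    n_isomorph_families: int = 30
    n_snp_alleles: int = 60
    n_indel_alleles: int = 30
    scenario_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # scenarios a/b/c
    window_size: int = 50_000
    window_overlap: int = 1_000
    edge_margin: int = 2_000  # keep planted variants away from window edges
    h2_snp: float = 0.25
    h2_indel: float = 0.10
    h2_orfs: float = 0.0
    h2_polygenic: float = 0.2


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# reference genome with genes and repeat tracts
# ---------------------------------------------------------------------------


def _random_cds_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_CODONS, n))


def _plant_gene(rng: np.random.Generator, strand: str):
    """A 3-exon gene (codon-boundary GT-AG introns, ATG start, canonical
    stop) as (plus-strand region sequence, exons, cds) relative intervals."""
    n1, n2, n3 = rng.integers(8, 20, 3)
    ex = [
        "ATG" + _random_cds_codons(rng, int(n1)),
        _random_cds_codons(rng, int(n2)),
        _random_cds_codons(rng, int(n3)) + str(rng.choice(["TAA", "TAG", "TGA"])),
    ]
    # splice sites carry the extended consensus real aligners key on
    introns = [
        "GTAAG" + random_dna(rng, int(rng.integers(12, 34))) + "TTCAG"
        for _ in range(2)
    ]
    gene_seq = ex[0] + introns[0] + ex[1] + introns[1] + ex[2]
    ivals = []
    offset = 0
    for k in range(3):
        ivals.append((offset, offset + len(ex[k])))
        offset += len(ex[k])
        if k < 2:
            offset += len(introns[k])
    if strand == "-":
        glen = len(gene_seq)
        region = revcomp(gene_seq)
        ivals = sorted((glen - e, glen - s) for s, e in ivals)
    else:
        region = gene_seq
    return region, ivals


@dataclass
class SyntheticReference:
    genome: ReferenceGenome
    models: dict[str, GeneModel]
    tracts: list[tuple[int, int, str]]  # (start, length, base) homopolymer runs


def gen_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> SyntheticReference:
    """Random chromosome with planted genes and homopolymer tracts.

    Genes alternate strands and sit in the central part of the chromosome;
    tracts (which enable position-shift isomorphs) are spread between them.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    length = config.chrom_length
    seq = list(random_dna(rng, length))
    models: dict[str, GeneModel] = {}
    tracts: list[tuple[int, int, str]] = []
    # genes evenly spaced, away from the chromosome ends
    gene_zone = (int(0.05 * length), int(0.95 * length))
    slots = np.linspace(gene_zone[0], gene_zone[1], config.n_genes + 1)[:-1]
    occupied: list[tuple[int, int]] = []
    for gi, slot in enumerate(slots):
        strand = "+" if gi % 2 == 0 else "-"
        region, ivals = _plant_gene(rng, strand)
        start = int(slot)
        end = start + len(region)
        if end > length:
            continue
        seq[start:end] = list(region)
        exons = [(start + s, start + e) for s, e in ivals]
        gid = f"gene{gi:03d}"
        models[gid] = GeneModel(gid, f"{gid}.t1", "chr1", strand, exons, list(exons))
        occupied.append((start - 1200, end + 1200))
    # homopolymer tracts in the gaps between (flanked) genes
    n_tracts = max(config.n_isomorph_families * 2, 20)
    attempts = 0
    while len(tracts) < n_tracts and attempts < n_tracts * 50:
        attempts += 1
        t_len = int(rng.integers(8, 15))
        pos = int(rng.integers(1000, length - 1000 - t_len))
        if any(lo - t_len < pos < hi for lo, hi in occupied):
            continue
        if any(abs(pos - p) < 60 for p, _, _ in tracts):
            continue
        base = str(rng.choice(list(_BASES)))
        seq[pos : pos + t_len] = [base] * t_len
        # break accidental tract extension at the borders
        other = _BASES.replace(base, "")
        seq[pos - 1] = other[int(rng.integers(0, 3))]
        seq[pos + t_len] = other[int(rng.integers(0, 3))]
        tracts.append((pos, t_len, base))
    tracts.sort()
    genome = ReferenceGenome(["chr1"], {"chr1": "".join(seq)})
    return SyntheticReference(genome, models, tracts)


# ---------------------------------------------------------------------------
# isomorph families
# ---------------------------------------------------------------------------


@dataclass
class IsomorphFamily:
    """One underlying allele with several sequence-equivalent representations."""

    family_id: str
    scenario: str  # a | b | c
    chrom: str
    region: tuple[int, int]
    representations: list[list[VariantCall]]  # sample field left blank
    carriers: list[str] = field(default_factory=list)


def _with_sample(calls: list[VariantCall], sample: str) -> list[VariantCall]:
    return [
        VariantCall(c.chrom, c.pos, c.ref_allele, c.alt_allele, sample)
        for c in calls
    ]


def _scenario_a(chrom: str, tract: tuple[int, int, str], rng) -> tuple[list, tuple]:
    """An INDEL placeable at multiple positions inside a repeat tract."""
    pos, t_len, base = tract
    d = int(rng.integers(2, min(5, t_len - 2)))
    left = [VariantCall(chrom, pos, base * d, "", "")]
    right = [VariantCall(chrom, pos + (t_len - d), base * d, "", "")]
    mid_off = (t_len - d) // 2
    mid = [VariantCall(chrom, pos + mid_off, base * d, "", "")]
    reps = [left, right] + ([mid] if mid != left and mid != right else [])
    return reps, (pos, pos + t_len)


def _scenario_b(chrom: str, seq: str, pos: int) -> tuple[list, tuple] | None:
    """The same haplotype as different variant *types*: a swap of two
    adjacent distinct bases XY -> YX as two SNPs or as insertion+deletion."""
    x, y = seq[pos], seq[pos + 1]
    if x == y:
        return None
    snps = [
        VariantCall(chrom, pos, x, y, ""),
        VariantCall(chrom, pos + 1, y, x, ""),
    ]
    indels = [
        VariantCall(chrom, pos, "", y, ""),  # insert Y before X
        VariantCall(chrom, pos + 1, y, "", ""),  # delete the original Y
    ]
    return [snps, indels], (pos, pos + 2)


def _scenario_c(chrom: str, seq: str, pos: int, rng) -> tuple[list, tuple] | None:
    """A complex substitution XYZ -> WV as one block replacement, or as
    {deletion + SNPs}, or as {SNPs + deletion}."""
    x, y, z = seq[pos : pos + 3]
    # replacement bases must differ from every base they substitute in any
    # representation, so no degenerate ref==alt SNP can be emitted
    w_choices = [b for b in _BASES if b not in (x, y)]
    v_choices = [b for b in _BASES if b not in (y, z)]
    w = w_choices[int(rng.integers(0, len(w_choices)))]
    v = v_choices[int(rng.integers(0, len(v_choices)))]
    block = [VariantCall(chrom, pos, x + y + z, w + v, "")]
    del_first = [
        VariantCall(chrom, pos, x, "", ""),
        VariantCall(chrom, pos + 1, y, w, ""),
        VariantCall(chrom, pos + 2, z, v, ""),
    ]
    del_last = [
        VariantCall(chrom, pos, x, w, ""),
        VariantCall(chrom, pos + 1, y, v, ""),
        VariantCall(chrom, pos + 2, z, "", ""),
    ]
    return [block, del_first, del_last], (pos, pos + 3)


def _forbidden_zones(chrom_len: int, config: SimulationConfig) -> list[tuple[int, int]]:
    zones = []
    m = config.edge_margin
    for w in make_windows(chrom_len, "chr1", config.window_size, config.window_overlap):
        if w.start > 0:
            zones.append((w.start - m, w.start + config.window_overlap + m))
    zones.append((0, 100))
    zones.append((chrom_len - 100, chrom_len))
    return zones


def gen_isomorph_population(
    ref: SyntheticReference,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SampleVariantSet], list[IsomorphFamily]]:
    """A population whose shared alleles arrive as mixed representations.

    Each family plants one underlying edit; every carrier receives one of the
    family's sequence-equivalent representations (all representations are
    verified during generation to edit the reference to the same string).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genome = ref.genome
    chrom = genome.chrom_names[0]
    seq = genome.sequences[chrom]
    chrom_len = len(seq)
    zones = _forbidden_zones(chrom_len, config)
    gene_spans = [(m.start - 1100, m.end + 1100) for m in ref.models.values()]

    def blocked(lo: int, hi: int) -> bool:
        for a, b in zones + gene_spans:
            if lo < b and a < hi:
                return True
        return False

    usable_tracts = [
        t for t in ref.tracts if not blocked(t[0] - 20, t[0] + t[1] + 20)
    ]
    rng.shuffle(usable_tracts)
    samples = [f"acc{k:03d}" for k in range(config.n_samples)]
    families: list[IsomorphFamily] = []
    used: list[tuple[int, int]] = []
    p_a, p_b, p_c = config.scenario_mix
    scen_draw = rng.random(config.n_isomorph_families * 3)
    tries = 0
    si = 0
    while len(families) < config.n_isomorph_families and tries < config.n_isomorph_families * 60:
        tries += 1
        u = scen_draw[si % len(scen_draw)]
        si += 1
        scenario = "a" if u < p_a else ("b" if u < p_a + p_b else "c")
        if scenario == "a":
            if not usable_tracts:
                scenario = "c"
            else:
                tract = usable_tracts.pop()
                reps, region = _scenario_a(chrom, tract, rng)
        if scenario in "bc":
            pos = int(rng.integers(200, chrom_len - 200))
            if blocked(pos - 20, pos + 20):
                continue
            made = (
                _scenario_b(chrom, seq, pos)
                if scenario == "b"
                else _scenario_c(chrom, seq, pos, rng)
            )
            if made is None:
                continue
            reps, region = made
        if any(lo - 30 < region[0] < hi + 30 or lo - 30 < region[1] < hi + 30 for lo, hi in used):
            continue
        used.append(region)
        fam = IsomorphFamily(
            f"fam{len(families):04d}", scenario, chrom, region, reps
        )
        # verify sequence equivalence of all representations
        lo = max(region[0] - 50, 0)
        hi = min(region[1] + 50, chrom_len)
        edited = set()
        for rep in reps:
            vs = SampleVariantSet("check")
            for c in _with_sample(rep, "check"):
                vs.add(c)
            vs.sort_and_validate(genome)
            hap, _ = apply_variants(genome, vs, chrom, lo, hi)
            edited.add(hap)
        if len(edited) != 1:
            raise AssertionError(f"{fam.family_id}: representations are not equivalent")
        # carriers: at least 2, drawn at an intermediate frequency
        n_car = max(2, int(round(len(samples) * rng.uniform(0.3, 0.7))))
        fam.carriers = list(rng.choice(samples, size=n_car, replace=False))
        families.append(fam)

    varsets = {s: SampleVariantSet(s) for s in samples}
    for fam in families:
        for k, s in enumerate(fam.carriers):
            rep = fam.representations[k % len(fam.representations)]
            for c in _with_sample(rep, s):
                varsets[s].add(c)
    out = []
    for s in samples:
        varsets[s].sort_and_validate(genome)
        out.append(varsets[s])
    return out, families


# ---------------------------------------------------------------------------
# plain shared-allele population (no isomorphs)
# ---------------------------------------------------------------------------


def gen_population(
    ref: SyntheticReference,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    avoid_genes: bool = True,
) -> tuple[list[SampleVariantSet], pd.DataFrame]:
    """Shared biallelic SNP and INDEL alleles at random positions with a
    single canonical representation each; returns varsets plus a truth table
    (position, kind, length, carriers)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genome = ref.genome
    chrom = genome.chrom_names[0]
    seq = genome.sequences[chrom]
    chrom_len = len(seq)
    zones = _forbidden_zones(chrom_len, config)
    if avoid_genes:
        zones = zones + [(m.start - 1100, m.end + 1100) for m in ref.models.values()]
    samples = [f"acc{k:03d}" for k in range(config.n_samples)]
    taken: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        for a, b in zones + taken:
            if lo < b and a < hi:
                return False
        return True

    alleles = []
    n_want = config.n_snp_alleles + config.n_indel_alleles
    tries = 0
    while len(alleles) < n_want and tries < n_want * 100:
        tries += 1
        is_snp = len(alleles) < config.n_snp_alleles
        pos = int(rng.integers(200, chrom_len - 200))
        span = 1 if is_snp else 12
        if not free(pos - span - 5, pos + span + 5):
            continue
        taken.append((pos - span - 5, pos + span + 5))
        if is_snp:
            ref_b = seq[pos]
            alt = _BASES[(_BASES.index(ref_b) + 1 + int(rng.integers(0, 3))) % 4]
            call = VariantCall(chrom, pos, ref_b, alt, "")
            kind, length = "snp", 1
        else:
            length = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                call = VariantCall(chrom, pos, seq[pos : pos + length], "", "")
                kind = "del"
            else:
                call = VariantCall(chrom, pos, "", random_dna(rng, length), "")
                kind = "ins"
        freq = rng.uniform(0.15, 0.85)
        carriers = [s for s in samples if rng.random() < freq]
        if len(carriers) in (0, len(samples)):
            continue
        alleles.append({"call": call, "kind": kind, "length": length, "carriers": carriers})

    varsets = {s: SampleVariantSet(s) for s in samples}
    rows = []
    for a in alleles:
        for s in a["carriers"]:
            for c in _with_sample([a["call"]], s):
                varsets[s].add(c)
        rows.append(
            {
                "chrom": chrom,
                "pos": a["call"].pos,
                "kind": a["kind"],
                "length": a["length"],
                "n_carriers": len(a["carriers"]),
                "carriers": ",".join(a["carriers"]),
            }
        )
    out = []
    for s in samples:
        varsets[s].sort_and_validate(genome)
        out.append(varsets[s])
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ORFS truth cases
# ---------------------------------------------------------------------------


def gen_orfs_cases(
    ref: SyntheticReference,
    n_cases: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[SampleVariantSet, str, str]]:
    """Gene x sample cases with known ORFS truth: frame-shifting CDS INDELs
    (length not divisible by 3) must come out interrupted; in-frame CDS edits
    and deep-intron edits conserved."""
    if rng is None:
        rng = np.random.default_rng(1234)
    genome = ref.genome
    seq = genome.sequences["chr1"]
    cases = []
    gene_ids = list(ref.models)
    for k in range(n_cases):
        model = ref.models[gene_ids[int(rng.integers(0, len(gene_ids)))]]
        mode = ("frameshift", "inframe", "intron")[int(rng.integers(0, 3))]
        vs = SampleVariantSet(f"case{k:04d}")
        if mode == "intron":
            intron = (model.exons[0][1], model.exons[1][0])
            pos = int(rng.integers(intron[0] + 4, intron[1] - 5))
            b = seq[pos]
            alt = _BASES[(_BASES.index(b) + 1) % 4]
            vs.add(VariantCall("chr1", pos, b, alt, vs.sample))
            expected = "conserved"
        else:
            length = int(rng.choice([1, 2, 4, 5] if mode == "frameshift" else [3, 6, 9]))
            exon = model.cds[int(rng.integers(0, len(model.cds)))]
            # keep away from start/stop codons and splice sites
            lo, hi = exon[0] + 6, exon[1] - 6 - length
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if rng.random() < 0.5:
                vs.add(VariantCall("chr1", pos, seq[pos : pos + length], "", vs.sample))
            else:
                vs.add(VariantCall("chr1", pos, "", random_dna(rng, length), vs.sample))
            expected = "interrupted" if mode == "frameshift" else "conserved"
            if mode == "inframe" and _inframe_edit_creates_stop(ref, model, vs):
                # an in-frame edit that happens to introduce a stop codon is a
                # genuine loss of function, not a conserved case: resample
                continue
        vs.sort_and_validate(genome)
        cases.append((vs, model.gene_id, expected))
    return cases


def _inframe_edit_creates_stop(ref: SyntheticReference, model, vs) -> bool:
    """True when an in-frame CDS edit introduces a premature stop codon."""
    from varsync.orfs import STOP_CODONS, annotate_by_liftover, extract_gene_haplotype

    hap = extract_gene_haplotype(ref.genome, vs, model, flank=50)
    lift = annotate_by_liftover(hap, model)
    cds = lift.spliced_cds(hap.seq)
    return any(cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3))


def gen_lof_population(
    ref: SyntheticReference,
    samples: list[str],
    rng: np.random.Generator,
    n_lof_genes: int = 2,
    independent: bool = True,
) -> tuple[dict[str, list[VariantCall]], pd.DataFrame]:
    """Plant loss-of-function alleles in genes.

    For each chosen gene, two disjoint carrier groups receive frame-shifting
    INDELs at two non-overlapping CDS positions (independent origins) or, with
    ``independent=False``, every carrier shares a single INDEL (one origin).
    Returns per-sample extra calls plus a truth table.
    """
    seq = ref.genome.sequences["chr1"]
    extra: dict[str, list[VariantCall]] = {s: [] for s in samples}
    rows = []
    gene_ids = list(ref.models)
    rng.shuffle(gene_ids)
    for gid in gene_ids[:n_lof_genes]:
        model = ref.models[gid]
        exon = max(model.cds, key=lambda iv: iv[1] - iv[0])
        lo, hi = exon[0] + 6, exon[1] - 12
        if hi - lo < 30:
            continue
        pos_a = int(rng.integers(lo, lo + (hi - lo) // 3))
        pos_b = int(rng.integers(lo + 2 * (hi - lo) // 3, hi))
        len_a, len_b = (int(x) for x in rng.choice([1, 2, 4, 5], 2))
        carriers = list(rng.choice(samples, size=max(4, len(samples) // 2), replace=False))
        half = len(carriers) // 2
        group_a, group_b = carriers[:half], carriers[half:]
        for s in group_a:
            extra[s].append(VariantCall("chr1", pos_a, seq[pos_a : pos_a + len_a], "", s))
        for s in group_b:
            if independent:
                extra[s].append(VariantCall("chr1", pos_b, seq[pos_b : pos_b + len_b], "", s))
            else:
                extra[s].append(VariantCall("chr1", pos_a, seq[pos_a : pos_a + len_a], "", s))
        rows.append(
            {
                "gene_id": gid,
                "pos_a": pos_a,
                "pos_b": pos_b if independent else pos_a,
                "independent": independent,
                "carriers": ",".join(carriers),
            }
        )
    return extra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def gen_genotype_matrix(
    n_samples: int,
    n_markers: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> np.ndarray:
    """Independent biallelic genotypes in {0,1} (no missingness)."""
    freqs = rng.uniform(*maf_range, size=n_markers)
    return (rng.random((n_samples, n_markers)) < freqs).astype(np.int8)


def gen_phenotypes(
    G: np.ndarray,
    causal: dict[str, list[int]],
    shares: dict[str, float],
    rng: np.random.Generator,
    K: np.ndarray | None = None,
    h2_polygenic: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Phenotype y = sum_c x_c beta_c + u + e with known variance shares.

    ``causal`` maps a class label to marker columns of ``G``; ``shares``
    gives each class's target fraction of the total phenotypic variance
    (split evenly over its causal markers).  The polygenic term is drawn
    from N(0, h2_polygenic * K); the residual takes the rest.
    """
    n = G.shape[0]
    total_genetic = sum(shares.values()) + h2_polygenic
    if total_genetic >= 1.0:
        raise ValueError("variance shares exceed 1")
    y = np.zeros(n)
    truth: dict = {"beta": {}}
    for cls, cols in causal.items():
        share = shares.get(cls, 0.0)
        if not cols or share <= 0:
            continue
        per = share / len(cols)
        for j in cols:
            x = G[:, j].astype(float)
            sd = x.std()
            if sd == 0:
                raise ValueError(f"causal marker {j} is monomorphic")
            beta = np.sqrt(per) / sd
            y += x * beta
            truth["beta"][(cls, j)] = beta
    if h2_polygenic > 0:
        if K is None:
            raise ValueError("polygenic share requires K")
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n)
        u *= np.sqrt(h2_polygenic) / max(u.std(), 1e-12)
        y += u
    resid_share = 1.0 - total_genetic
    e = rng.standard_normal(n)
    y += e * np.sqrt(resid_share)
    truth["shares"] = dict(shares)
    truth["h2_polygenic"] = h2_polygenic
    return y, truth


# ---------------------------------------------------------------------------
# loss-of-function power simulation
# ---------------------------------------------------------------------------


def _ranksum_p(groups_a: np.ndarray, groups_b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, vectorised over replicate rows
    (normal approximation, matching scipy.stats.ranksums)."""
    n1 = groups_a.shape[1]
    n2 = groups_b.shape[1]
    both = np.concatenate([groups_a, groups_b], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n1 + n2 + 1) / 2.0
    z = (r1 - expected) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def simulate_lof_power(
    n_per_allele: int = 70,
    mu_functional: float = 2.0,
    mu_lof: float = 1.0,
    var: float = 1.44,
    reps: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Power comparison of a single-INDEL test versus the combined ORFS test.

    Three allele groups of ``n_per_allele`` samples each: a functional allele
    with phenotype mean ``mu_functional``, and two loss-of-function alleles
    (each disrupted by a different INDEL) with mean ``mu_lof``; all draws
    have variance ``var``.  Per replicate, the single-INDEL test compares
    carriers of one INDEL against everyone else, while the ORFS test pools
    both loss-of-function groups; both use the two-sided Wilcoxon rank-sum
    test.  Returns per-replicate p-values for both tests.
    """
    rng = np.random.default_rng(seed)
    sd = np.sqrt(var)
    g1 = rng.normal(mu_functional, sd, size=(reps, n_per_allele))
    g2 = rng.normal(mu_lof, sd, size=(reps, n_per_allele))
    g3 = rng.normal(mu_lof, sd, size=(reps, n_per_allele))
    p_indel = _ranksum_p(g2, np.concatenate([g1, g3], axis=1))
    p_orfs = _ranksum_p(np.concatenate([g2, g3], axis=1), g1)
    return pd.DataFrame({"p_single_indel": p_indel, "p_orfs": p_orfs})


def lof_power_summary(pvals: pd.DataFrame, threshold_log10p: float = 7.8) -> dict:
    """Median -log10 p and genome-wide exceedance rate for both tests."""
    eps = 1e-300
    l_indel = -np.log10(np.maximum(pvals.p_single_indel.values, eps))
    l_orfs = -np.log10(np.maximum(pvals.p_orfs.values, eps))
    return {
        "median_neglog10p_single_indel": float(np.median(l_indel)),
        "median_neglog10p_orfs": float(np.median(l_orfs)),
        "exceed_single_indel": float((l_indel > threshold_log10p).mean()),
        "exceed_orfs": float((l_orfs > threshold_log10p).mean()),
        "threshold_log10p": threshold_log10p,
    }
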