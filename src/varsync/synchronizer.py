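"""Population-wide variant synchronization by windowed multiple sequence alignment.

The same underlying haplotype difference can be reported as several distinct
but sequence-equivalent variant representations ("alignment isomorphs"),
which show up in a population as spurious multi-allelic sites.  The
synchronizer removes them by re-calling all variants from a joint alignment:

1. the reference is split into overlapping windows (default 50 kb windows
   overlapping by 1 kb) and each sample's haplotype is reconstructed from its
   input calls;
2. reference + all haplotype window slices are multiply aligned;
3. variants are called from the alignment column by column as *atomic*
   1-bp units (a 10-bp deletion becomes ten 1-bp deletions), conflicts in
   window overlaps are resolved in favour of the call closer to its window
   center, and atomic runs are merged back into full INDEL records.

Because step 2 sees only the haplotype *sequence*, all input representations
of one allele collapse to a single shared call.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from varsync.core_io import (
    ReferenceGenome,
    SampleVariantSet,
    VariantCall,
    apply_variants,
)

GAP = ord("-")


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    index: int

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class WindowAlignment:
    """MSA of reference (row 0) + sample haplotypes over one window."""

    window: Window
    rows: list[str]
    row_samples: list[str]  # parallel to rows[1:]

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")


@dataclass(frozen=True)
class AtomicVariant:
    """One 1-bp unit called from a single MSA column.

    For ``ins1`` the position is the insertion point (the variant precedes
    reference base ``ref_pos``) and ``ins_offset`` is the ordinal of this base
    among the sample's insertions at the same anchor.
    """

    chrom: str
    ref_pos: int
    kind: str  # snp | del1 | ins1
    base: str  # alt base (snp/ins1) or deleted base (del1)
    ref_base: str
    sample: str
    window_index: int
    ins_offset: int = 0


@dataclass
class SyncConfig:
    window_size: int = 50_000
    window_overlap: int = 1_000
    aligner: str = "builtin"  # builtin | mafft
    mafft_path: str = "mafft"


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(
    chrom_len: int, chrom: str = "", window: int = 50_000, overlap: int = 1_000
) -> list[Window]:
    """Overlapping windows covering [0, chrom_len); step = window - overlap."""
    if window <= overlap or overlap < 0:
        raise ValueError(f"window ({window}) must exceed overlap ({overlap}) >= 0")
    windows = []
    start = 0
    step = window - overlap
    while True:
        end = min(start + window, chrom_len)
        windows.append(Window(chrom, start, end, len(windows)))
        if end >= chrom_len:
            break
        start += step
    return windows


# ---------------------------------------------------------------------------
# alignment engines
# ---------------------------------------------------------------------------


def _pairwise_edlib(ref: str, hap: str) -> tuple[np.ndarray, list[str]]:
    """Globally align one haplotype to the reference slice.

    Returns ``aligned`` (len(ref) array of the haplotype byte aligned to each
    reference base, gap where deleted) and ``inserts`` (len(ref)+1 list of
    inserted text before each reference position).
    """
    import edlib

    nref = len(ref)
    aligned = np.full(nref, GAP, dtype=np.uint8)
    inserts = [""] * (nref + 1)
    if not hap:
        return aligned, inserts
    res = edlib.align(hap, ref, task="path", mode="NW")
    cigar = res["cigar"]
    hap_b = hap.encode()
    i = 0  # haplotype cursor
    j = 0  # reference cursor
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        if ch in "=X":
            aligned[j : j + num] = np.frombuffer(hap_b[i : i + num], dtype=np.uint8)
            i += num
            j += num
        elif ch == "D":  # extra reference bases: deletion in the sample
            j += num
        elif ch == "I":  # extra haplotype bases: insertion
            inserts[j] += hap[i : i + num]
            i += num
        num = 0
    return aligned, inserts


def _builtin_msa(ref: str, haps: list[str]) -> list[str]:
    """Reference-guided MSA: pairwise global alignments merged by the union of
    their insertion columns.  Row content depends only on haplotype sequence,
    so equivalent input representations always produce identical rows."""
    pairwise = [_pairwise_edlib(ref, h) for h in haps]
    nref = len(ref)
    max_ins = np.zeros(nref + 1, dtype=np.int64)
    for _, inserts in pairwise:
        for p, text in enumerate(inserts):
            if len(text) > max_ins[p]:
                max_ins[p] = len(text)
    rows = []
    # reference row
    parts = []
    for p in range(nref):
        parts.append("-" * max_ins[p])
        parts.append(ref[p])
    parts.append("-" * max_ins[nref])
    rows.append("".join(parts))
    for aligned, inserts in pairwise:
        parts = []
        for p in range(nref):
            ins = inserts[p]
            parts.append(ins + "-" * (max_ins[p] - len(ins)))
            parts.append(chr(aligned[p]))
        ins = inserts[nref]
        parts.append(ins + "-" * (max_ins[nref] - len(ins)))
        rows.append("".join(parts))
    return rows


def _mafft_msa(ref: str, haps: list[str], mafft_path: str = "mafft") -> list[str]:
    """External MSA engine (``mafft --auto``); same row contract as builtin."""
    if shutil.which(mafft_path) is None:
        raise RuntimeError(f"mafft executable not found: {mafft_path}")
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        fh.write(">ref\n" + ref + "\n")
        for k, h in enumerate(haps):
            fh.write(f">s{k}\n" + (h or "N") + "\n")  # mafft rejects empty records
        path = fh.name
    out = subprocess.run(
        [mafft_path, "--auto", "--quiet", path],
        check=True,
        capture_output=True,
        text=True,
    ).stdout
    seqs: dict[str, str] = {}
    name = None
    for line in out.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    rows = [seqs["ref"].upper()]
    for k, h in enumerate(haps):
        row = seqs[f"s{k}"].upper()
        rows.append(row if h else "-" * len(row))
    return rows


def align_window(
    ref_slice: str,
    haplotypes: list[str],
    samples: list[str],
    window: Window,
    config: SyncConfig | None = None,
) -> WindowAlignment:
    """Multiply align reference + haplotype slices for one window."""
    config = config or SyncConfig()
    if config.aligner == "builtin":
        rows = _builtin_msa(ref_slice, haplotypes)
    elif config.aligner == "mafft":
        rows = _mafft_msa(ref_slice, haplotypes, config.mafft_path)
    else:
        raise ValueError(f"unknown aligner {config.aligner!r}")
    aln = WindowAlignment(window, rows, list(samples))
    if rows[0].replace("-", "") != ref_slice:
        raise RuntimeError("alignment engine corrupted the reference row")
    for row, hap in zip(rows[1:], haplotypes):
        if row.replace("-", "") != hap:
            raise RuntimeError("alignment engine corrupted a haplotype row")
    return aln


# ---------------------------------------------------------------------------
# atomic calling
# ---------------------------------------------------------------------------


def call_atomic(aln: WindowAlignment) -> list[AtomicVariant]:
    """Call variants from the MSA column by column as 1-bp atomic units."""
    w = aln.window
    ref = np.frombuffer(aln.rows[0].encode(), dtype=np.uint8)
    ref_gap = ref == GAP
    ref_n = ref == ord("N")
    # reference offset consumed at each reference-consuming column
    consumed = np.cumsum(~ref_gap)
    ref_idx = consumed - 1  # valid where ~ref_gap
    ins_point = consumed  # insertion point at reference-gap columns
    out: list[AtomicVariant] = []
    for row, sample in zip(aln.rows[1:], aln.row_samples):
        s = np.frombuffer(row.encode(), dtype=np.uint8)
        s_gap = s == GAP
        s_n = s == ord("N")
        del_cols = np.flatnonzero(~ref_gap & s_gap)
        # N bases never produce SNP calls (no reliable match/mismatch)
        snp_cols = np.flatnonzero(~ref_gap & ~s_gap & (s != ref) & ~ref_n & ~s_n)
        ins_cols = np.flatnonzero(ref_gap & ~s_gap)
        for c in del_cols:
            out.append(
                AtomicVariant(
                    w.chrom, w.start + int(ref_idx[c]), "del1",
                    chr(ref[c]), chr(ref[c]), sample, w.index,
                )
            )
        for c in snp_cols:
            out.append(
                AtomicVariant(
                    w.chrom, w.start + int(ref_idx[c]), "snp",
                    chr(s[c]), chr(ref[c]), sample, w.index,
                )
            )
        if len(ins_cols):
            anchors = ins_point[ins_cols]
            _, first = np.unique(anchors, return_index=True)
            counts = np.diff(np.append(first, len(anchors)))
            offsets = np.arange(len(anchors)) - np.repeat(first, counts)
            for c, anchor, off in zip(ins_cols, anchors, offsets):
                out.append(
                    AtomicVariant(
                        w.chrom, w.start + int(anchor), "ins1",
                        chr(s[c]), "", sample, w.index, ins_offset=int(off),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# overlap resolution and merging
# ---------------------------------------------------------------------------


def resolve_overlaps(
    atomics_by_window: list[list[AtomicVariant]], windows: list[Window]
) -> list[AtomicVariant]:
    """Keep, for each reference position, the calls of the window whose center
    is nearest (ties go to the earlier window).

    Every position is owned by exactly one window, so agreeing duplicate
    calls in overlaps are deduplicated and conflicts are resolved at once.
    """
    cuts = []  # window i owns positions <= cuts[i]
    for a, b in zip(windows, windows[1:]):
        # nearest-center midpoint, clamped into the region both windows see:
        # positions only one window covers always belong to that window
        cut = (a.center + b.center) // 2
        cuts.append(min(max(cut, b.start - 1), a.end - 1))
    cuts.append(np.iinfo(np.int64).max)
    lo = -1
    kept: list[AtomicVariant] = []
    for w, atomics in zip(windows, atomics_by_window):
        hi = cuts[w.index]
        for a in atomics:
            if lo < a.ref_pos <= hi:
                kept.append(a)
        lo = hi
    return kept


def merge_atomic(atomics: list[AtomicVariant]) -> dict[str, list[VariantCall]]:
    """Merge atomic runs into full variant records, per sample.

    Runs of 1-bp deletions at consecutive positions become one deletion; runs
    of 1-bp insertions at one anchor become one insertion; SNPs stay atomic.
    Overlapping INDELs (an insertion anchored inside a deleted span) remain
    two independent records, so deletion runs are merged irrespective of any
    interleaved insertion anchors.
    """
    by_sample: dict[str, list[AtomicVariant]] = {}
    for a in atomics:
        by_sample.setdefault(a.sample, []).append(a)
    out: dict[str, list[VariantCall]] = {}
    for sample, items in by_sample.items():
        calls: list[VariantCall] = []
        snps = [a for a in items if a.kind == "snp"]
        dels = sorted((a for a in items if a.kind == "del1"), key=lambda a: (a.chrom, a.ref_pos))
        inss = sorted(
            (a for a in items if a.kind == "ins1"),
            key=lambda a: (a.chrom, a.ref_pos, a.ins_offset),
        )
        for a in snps:
            calls.append(VariantCall(a.chrom, a.ref_pos, a.ref_base, a.base, sample))
        i = 0
        while i < len(dels):
            j = i + 1
            while (
                j < len(dels)
                and dels[j].chrom == dels[i].chrom
                and dels[j].ref_pos == dels[j - 1].ref_pos + 1
            ):
                j += 1
            ref = "".join(x.base for x in dels[i:j])
            calls.append(VariantCall(dels[i].chrom, dels[i].ref_pos, ref, "", sample))
            i = j
        i = 0
        while i < len(inss):
            j = i + 1
            while (
                j < len(inss)
                and inss[j].chrom == inss[i].chrom
                and inss[j].ref_pos == inss[i].ref_pos
                and inss[j].ins_offset == inss[j - 1].ins_offset + 1
            ):
                j += 1
            alt = "".join(x.base for x in inss[i:j])
            calls.append(VariantCall(inss[i].chrom, inss[i].ref_pos, "", alt, sample))
            i = j
        calls.sort(key=lambda c: (c.chrom, c.pos, c.end, c.is_insertion))
        out[sample] = calls
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class SyncResult:
    samples: list[str]
    varsets: dict[str, SampleVariantSet]
    markers: pd.DataFrame  # chrom, pos, kind, length, ref, alt
    genotypes: np.ndarray  # samples x markers, int8 in {0, 1}
    report: pd.DataFrame

    def marker_key(self) -> pd.Index:
        return pd.Index(
            list(zip(self.markers.chrom, self.markers.pos, self.markers.kind, self.markers.length))
        )


def _marker_key(c: VariantCall) -> tuple:
    """Marker identity: SNPs by (pos, alt); INDELs by (pos, length, type) —
    two insertions of equal length at one point are the same marker even if
    the inserted text differs."""
    if c.is_snp:
        return (c.chrom, c.pos, "snp", 1, c.alt_allele)
    if c.is_insertion:
        return (c.chrom, c.pos, "ins", len(c.alt_allele), "")
    if c.is_deletion:
        return (c.chrom, c.pos, "del", len(c.ref_allele), "")
    return (c.chrom, c.pos, "sub", len(c.ref_allele), c.alt_allele)


def synchronize_population(
    genome: ReferenceGenome,
    varsets: list[SampleVariantSet],
    config: SyncConfig | None = None,
) -> SyncResult:
    """Run the full windows -> haplotypes -> MSA -> atomic -> resolve -> merge
    pipeline over every chromosome and assemble the synchronized population
    variant table plus a per-sample reassignment report."""
    config = config or SyncConfig()
    samples = [vs.sample for vs in varsets]
    merged: dict[str, list[VariantCall]] = {s: [] for s in samples}
    for chrom in genome.chrom_names:
        ref_seq = genome.sequences[chrom]
        chrom_len = len(ref_seq)
        haps = []
        maps = []
        for vs in varsets:
            hap, cmap = apply_variants(genome, vs, chrom, 0, chrom_len)
            haps.append(hap)
            maps.append(cmap)
        windows = make_windows(chrom_len, chrom, config.window_size, config.window_overlap)
        atomics_by_window = []
        for w in windows:
            ref_slice = ref_seq[w.start : w.end]
            hap_slices = [
                hap[cmap.ref2hap[w.start] : cmap.ref2hap[w.end]]
                for hap, cmap in zip(haps, maps)
            ]
            aln = align_window(ref_slice, hap_slices, samples, w, config)
            atomics_by_window.append(call_atomic(aln))
        resolved = resolve_overlaps(atomics_by_window, windows)
        for sample, calls in merge_atomic(resolved).items():
            merged[sample].extend(calls)

    out_sets = {}
    for s in samples:
        vs = SampleVariantSet(s)
        for c in merged[s]:
            vs.add(c)
        vs.sort_and_validate()
        out_sets[s] = vs

    # population marker table
    marker_map: dict[tuple, dict] = {}
    for si, s in enumerate(samples):
        for c in merged[s]:
            key = _marker_key(c)
            rec = marker_map.setdefault(
                key,
                {
                    "chrom": key[0], "pos": key[1], "kind": key[2],
                    "length": key[3], "ref": c.ref_allele,
                    "alts": {}, "carriers": [],
                },
            )
            rec["carriers"].append(si)
            rec["alts"][c.alt_allele] = rec["alts"].get(c.alt_allele, 0) + 1
    keys = sorted(marker_map, key=lambda k: (k[0], k[1], k[2], k[3], k[4]))
    rows = []
    genotypes = np.zeros((len(samples), len(keys)), dtype=np.int8)
    for mi, key in enumerate(keys):
        rec = marker_map[key]
        alt = max(rec["alts"].items(), key=lambda kv: (kv[1], kv[0]))[0]
        rows.append(
            {
                "chrom": rec["chrom"], "pos": rec["pos"], "kind": rec["kind"],
                "length": rec["length"], "ref": rec["ref"], "alt": alt,
            }
        )
        genotypes[rec["carriers"], mi] = 1
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "kind", "length", "ref", "alt"])

    report = _reassignment_report(varsets, out_sets)
    return SyncResult(samples, out_sets, markers, genotypes, report)


def _indel_signatures(vs: SampleVariantSet) -> tuple[set, set]:
    """(full representation, (type, length)-only) signatures of INDEL calls."""
    full, typed = set(), set()
    for calls in vs.calls.values():
        for c in calls:
            if c.is_indel:
                full.add((c.chrom, c.pos, c.ref_allele, c.alt_allele))
                kind = "ins" if len(c.alt_allele) > len(c.ref_allele) else "del"
                typed.add((c.chrom, kind, abs(len(c.alt_allele) - len(c.ref_allele))))
    return full, typed


def _reassignment_report(
    inputs: list[SampleVariantSet], outputs: dict[str, SampleVariantSet]
) -> pd.DataFrame:
    """Per sample, the fraction of input INDELs whose synchronized
    representation differs from the input (reassigned to a shared allele).
    ``n_moved_same_length`` counts the subset where an INDEL of identical type
    and length still exists elsewhere (pure position shifts)."""
    rows = []
    for vs in inputs:
        out = outputs[vs.sample]
        out_full, _ = _indel_signatures(out)
        out_typed_positions: set = set()
        for calls in out.calls.values():
            for c in calls:
                if c.is_indel:
                    kind = "ins" if len(c.alt_allele) > len(c.ref_allele) else "del"
                    out_typed_positions.add(
                        (c.chrom, kind, abs(len(c.alt_allele) - len(c.ref_allele)))
                    )
        n_input = 0
        n_reassigned = 0
        n_moved = 0
        for calls in vs.calls.values():
            for c in calls:
                if not c.is_indel:
                    continue
                n_input += 1
                if (c.chrom, c.pos, c.ref_allele, c.alt_allele) not in out_full:
                    n_reassigned += 1
                    kind = "ins" if len(c.alt_allele) > len(c.ref_allele) else "del"
                    if (c.chrom, kind, abs(len(c.alt_allele) - len(c.ref_allele))) in out_typed_positions:
                        n_moved += 1
        rows.append(
            {
                "sample": vs.sample,
                "n_input_indels": n_input,
                "n_reassigned": n_reassigned,
                "n_moved_same_length": n_moved,
                "fraction_reassigned": (n_reassigned / n_input) if n_input else 0.0,
            }
        )
    return pd.DataFrame(rows)
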