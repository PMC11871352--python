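"""Synthetic annotated mitogenomes and simulated codon alignments.

The genome generator emulates the canonical vertebrate mitogenome
layout — 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one control
region, mixed-strand encoding, incomplete stop codons — with tunable
A+T content and strand skews, and a control region carrying planted
tandem repeats and conserved-block motifs whose ground-truth
coordinates are returned alongside the record.  Codon alignments evolve
under the GY94 process on a fixed tree with per-site ω classes, using
exact transition probabilities (spectral, not Gillespie), so simulated
data can be cross-checked against the likelihood machinery they test.

Everything is a pure function of (spec, seed): same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetic_code import VERTEBRATE_MITO, GeneticCode
from .mito_io import (
    GeneFeature,
    MitogenomeRecord,
    load_printed_table,
    reverse_complement,
    write_genbank,
)
from .selection.alignment import CodonAlignment
from .selection.gy94 import decompose, pi_from_nt_freqs, rate_matrix, structure
from .selection.trees import from_newick

_BASES = ("A", "C", "G", "T")


@dataclass
class GeneTemplate:
    name: str
    element_class: str
    strand: str
    length: int
    start_codon: str = "ATG"
    stop_codon: str = "TAA"  # or T--/TA- for incomplete
    anticodon: str | None = None


@dataclass
class PlantedRepeat:
    motif: str
    copies: float
    offset: int  # 0-based offset within the control region
    identity: float = 100.0


@dataclass
class PlantedBlock:
    name: str
    motif: str  # concrete (non-degenerate) instance to plant
    offset: int


@dataclass
class ControlRegionSpec:
    length: int
    repeats: list[PlantedRepeat] = field(default_factory=list)
    blocks: list[PlantedBlock] = field(default_factory=list)


@dataclass
class GenomeSpec:
    """Recipe for one synthetic circular mitogenome."""

    gene_order: list[GeneTemplate]
    cr: ControlRegionSpec
    seed: int
    accession: str = "SYN000001"
    target_at: float = 0.615
    target_at_skew: float = 0.145
    target_gc_skew: float = -0.376
    intergenic: int = 0  # spacer between consecutive elements


def strand_probabilities(
    at: float, at_skew: float, gc_skew: float
) -> dict[str, float]:
    """Per-base draw probabilities realizing an AT fraction and skews.

    P(A)=at(1+sAT)/2, P(T)=at(1−sAT)/2 and likewise for G/C; raises if
    the combination leaves any probability outside [0, 1].
    """
    if not 0.0 < at < 1.0:
        raise ValueError(f"infeasible composition targets: AT fraction {at}")
    probs = {
        "A": at * (1 + at_skew) / 2,
        "T": at * (1 - at_skew) / 2,
        "G": (1 - at) * (1 + gc_skew) / 2,
        "C": (1 - at) * (1 - gc_skew) / 2,
    }
    if not all(0.0 <= p <= 1.0 for p in probs.values()):
        raise ValueError(
            f"infeasible composition targets: at={at}, skews="
            f"({at_skew}, {gc_skew}) give {probs}"
        )
    return probs


def _complement_probs(probs: dict[str, float]) -> dict[str, float]:
    return {"A": probs["T"], "T": probs["A"], "G": probs["C"], "C": probs["G"]}


def _draw(rng: np.random.Generator, probs: dict[str, float], n: int) -> str:
    p = np.array([probs[b] for b in _BASES])
    return "".join(rng.choice(_BASES, size=n, p=p / p.sum()))


def _sense_codon_distribution(
    probs: dict[str, float], code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    """An iid sense-codon distribution whose base marginals match `probs`.

    Excluding stop codons from a product-of-bases draw would shift the
    realized composition (stops are A/T-rich), so the underlying base
    weights are adjusted by fixed-point iteration until the conditional
    distribution's average per-position marginal hits the target.
    """
    sense = list(code.sense_codons)
    target = np.array([probs[b] for b in _BASES])
    target = target / target.sum()
    idx = np.array([[_BASES.index(ch) for ch in c] for c in sense])
    q = target.copy()
    for _ in range(200):
        p = q[idx[:, 0]] * q[idx[:, 1]] * q[idx[:, 2]]
        p = p / p.sum()
        marginal = np.zeros(4)
        for pos in range(3):
            np.add.at(marginal, idx[:, pos], p / 3.0)
        if np.abs(marginal - target).max() < 1e-12:
            break
        q = q * (target / np.maximum(marginal, 1e-12))
        q = q / q.sum()
    p = q[idx[:, 0]] * q[idx[:, 1]] * q[idx[:, 2]]
    return sense, p / p.sum()


def _draw_codons(
    rng: np.random.Generator, probs: dict[str, float], n: int,
    code: GeneticCode,
) -> str:
    """n sense codons drawn iid, marginally matching the base targets."""
    sense, p = _sense_codon_distribution(probs, code)
    return "".join(np.array(sense)[rng.choice(len(sense), size=n, p=p)])


def default_gene_order() -> list[GeneTemplate]:
    """The canonical vertebrate element order, classes, strands and sizes
    (the shipped soft-shelled-turtle coordinate table supplies the
    pattern; sequences are never copied)."""
    rec = load_printed_table("palea_steindachneri")
    out = []
    for f in rec.features:
        if f.element_class == "CR":
            continue
        length = f.size(rec.length)
        stop = f.stop_codon or "TAA"
        # keep the template realizable: an incomplete stop occupies
        # exactly length mod 3 trailing nucleotides
        if length % 3 == 1:
            stop = "T--"
        elif length % 3 == 2:
            stop = "TA-"
        elif "-" in stop:
            stop = "TAA"
        out.append(
            GeneTemplate(
                name=f.name, element_class=f.element_class, strand=f.strand,
                length=length,
                start_codon=f.start_codon or "ATG",
                stop_codon=stop,
                anticodon=f.anticodon,
            )
        )
    return out


def default_control_region() -> ControlRegionSpec:
    """A 1.3 kb control region with two repeat arrays (long 5' motif,
    short A/T-rich 3' microsatellite) and an ETAS1 + CSB-1/2/3 set."""
    return ControlRegionSpec(
        length=1305,
        repeats=[
            PlantedRepeat(
                motif="ATTTTACTTTTTTTTCTCTCCCGCGCCCAAGAGATATAAAACCCCTGTAT",
                copies=5.0, offset=0,
            ),
            PlantedRepeat(motif="ATATT", copies=33.0, offset=1138),
        ],
        blocks=[
            PlantedBlock(name="ETAS1", motif="GCACAT", offset=330),
            PlantedBlock(name="CSB-1", motif="TTAATGCTTGTAGGACATA", offset=600),
            PlantedBlock(name="CSB-2", motif="CAAACCCCCCCTCCCCC", offset=700),
            PlantedBlock(name="CSB-3", motif="TGCCAAACCCCAAAAACAA", offset=760),
        ],
    )


def default_genome_spec(seed: int) -> GenomeSpec:
    return GenomeSpec(
        gene_order=default_gene_order(),
        cr=default_control_region(),
        seed=seed,
        accession=f"SYN{seed:06d}",
    )


def _build_control_region(
    spec: ControlRegionSpec, rng: np.random.Generator,
    probs: dict[str, float],
) -> tuple[str, list[dict]]:
    seq = list(_draw(rng, probs, spec.length))
    truth: list[dict] = []
    for rep in spec.repeats:
        p = len(rep.motif)
        span = int(round(rep.copies * p))
        if rep.offset + span > spec.length:
            raise ValueError(
                f"repeat {rep.motif!r} x{rep.copies} overruns the control "
                "region"
            )
        array = (rep.motif * (int(np.ceil(rep.copies)) + 1))[:span]
        array = list(array)
        n_mut = int(round((1.0 - rep.identity / 100.0) * span))
        mut_pos = rng.choice(span, size=n_mut, replace=False) if n_mut else []
        for i in mut_pos:
            array[i] = rng.choice([b for b in _BASES if b != array[i]])
        seq[rep.offset: rep.offset + span] = array
        truth.append({
            "kind": "repeat", "motif": rep.motif, "period": p,
            "copies": round(span / p, 1), "cr_start": rep.offset + 1,
            "cr_end": rep.offset + span, "identity": rep.identity,
        })
    for blk in spec.blocks:
        end = blk.offset + len(blk.motif)
        if end > spec.length:
            raise ValueError(f"block {blk.name} overruns the control region")
        seq[blk.offset: end] = list(blk.motif)
        truth.append({
            "kind": "block", "name": blk.name, "motif": blk.motif,
            "cr_start": blk.offset + 1, "cr_end": end,
        })
    return "".join(seq), truth


def generate_mitogenome(
    spec: GenomeSpec,
    genbank_path: str | Path | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
) -> tuple[MitogenomeRecord, dict]:
    """Generate an annotated mitogenome and its ground-truth record.

    Per-element coding sequences are drawn from base probabilities that
    realize the target composition on the reference strand (H-strand
    elements draw from the complementary distribution before being
    reverse-complemented into place); PCGs are open reading frames with
    the template's start/stop codons, incomplete stops included.
    """
    rng = np.random.default_rng(spec.seed)
    probs_ref = strand_probabilities(
        spec.target_at, spec.target_at_skew, spec.target_gc_skew
    )
    probs_h = _complement_probs(probs_ref)

    chunks: list[str] = []
    features: list[GeneFeature] = []
    truth_features: list[dict] = []
    cr_truth: list[dict] = []
    pos = 0  # 0-based length so far

    def _append(template_seq_ref: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        chunks.append(template_seq_ref)
        pos += len(template_seq_ref)
        return start, pos

    for i, g in enumerate(spec.gene_order + [None]):  # None = control region
        if spec.intergenic and i > 0:
            _append(_draw(rng, probs_ref, spec.intergenic))
        if g is None:
            probs = probs_ref  # CR annotated on the reference strand
            cr_seq, cr_truth = _build_control_region(spec.cr, rng, probs)
            start, end = _append(cr_seq)
            features.append(
                GeneFeature(name="control_region", element_class="CR",
                            strand="L", start=start, end=end)
            )
            continue
        probs = probs_ref if g.strand == "L" else probs_h
        if g.element_class == "PCG":
            stop = g.stop_codon
            if "-" in stop:
                tail = stop.replace("-", "")
                n_body = (g.length - 3 - len(tail)) // 3
                seq = g.start_codon + _draw_codons(rng, probs, n_body, code) + tail
            else:
                n_body = (g.length - 6) // 3
                seq = g.start_codon + _draw_codons(rng, probs, n_body, code) + stop
            if len(seq) != g.length:
                raise ValueError(
                    f"{g.name}: length {g.length} incompatible with "
                    f"start/stop {g.start_codon}/{g.stop_codon}"
                )
        else:
            seq = _draw(rng, probs, g.length)
        ref_seq = seq if g.strand == "L" else reverse_complement(seq)
        start, end = _append(ref_seq)
        features.append(
            GeneFeature(
                name=g.name, element_class=g.element_class, strand=g.strand,
                start=start, end=end, anticodon=g.anticodon,
            )
        )
        truth_features.append({
            "name": g.name, "class": g.element_class, "strand": g.strand,
            "start": start, "end": end,
            "start_codon": g.start_codon if g.element_class == "PCG" else None,
            "stop_codon": g.stop_codon if g.element_class == "PCG" else None,
        })

    sequence = "".join(chunks)
    record = MitogenomeRecord(
        accession=spec.accession, length=len(sequence), sequence=sequence,
        features=features, circular=True,
    )
    cr_feat = record.features_of_class("CR")[0]
    for t in cr_truth:
        t["genome_start"] = cr_feat.start + t["cr_start"] - 1
        t["genome_end"] = cr_feat.start + t["cr_end"] - 1
    truth = {
        "seed": spec.seed,
        "targets": {
            "at": spec.target_at, "at_skew": spec.target_at_skew,
            "gc_skew": spec.target_gc_skew,
        },
        "features": truth_features,
        "control_region": cr_truth,
    }
    if genbank_path is not None:
        write_genbank(record, genbank_path)
    return record, truth


# ---------------------------------------------------------------------------
# codon alignment simulation

@dataclass
class SimAlignmentSpec:
    """Recipe for a GY94 simulation on a fixed tree.

    `omega` may be a single ratio, a mixture [(weight, omega), ...] with
    per-site classes drawn from the weights, or an explicit per-site
    list of ratios.
    """

    newick: str
    n_codons: int
    kappa: float
    omega: float | list
    seed: int
    nt_freqs: dict[str, float] = field(
        default_factory=lambda: {"T": 0.28, "C": 0.26, "A": 0.32, "G": 0.14}
    )
    code: GeneticCode = field(default=VERTEBRATE_MITO)


def simulate_codon_alignment(spec: SimAlignmentSpec) -> tuple[CodonAlignment, dict]:
    """Evolve codons along the tree; returns the alignment plus per-site
    true ω assignments."""
    if spec.n_codons < 1:
        raise ValueError("n_codons must be positive")
    tree = from_newick(spec.newick)
    if any(t < 0 for t in tree.branch_lengths):
        raise ValueError("negative branch length")
    rng = np.random.default_rng(spec.seed)
    st = structure(spec.code)
    pi = pi_from_nt_freqs(spec.nt_freqs, spec.code)

    if isinstance(spec.omega, (int, float)):
        site_omega = np.full(spec.n_codons, float(spec.omega))
    elif spec.omega and isinstance(spec.omega[0], (tuple, list)):
        weights = np.array([w for w, _ in spec.omega], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        omegas = np.array([om for _, om in spec.omega], dtype=float)
        site_omega = omegas[rng.choice(len(omegas), size=spec.n_codons, p=weights)]
    else:
        site_omega = np.asarray(spec.omega, dtype=float)
        if len(site_omega) != spec.n_codons:
            raise ValueError("per-site omega list length != n_codons")

    distinct = np.unique(site_omega)
    # normalize branch lengths by the rate averaged over realized sites
    rates = {}
    Qs = {}
    for om in distinct:
        Q, r = rate_matrix(spec.kappa, float(om), pi, st)
        Qs[om], rates[om] = Q, r
    scale = float(np.mean([rates[om] for om in site_omega]))
    if scale <= 0:
        scale = 1.0  # omega==0 with no synonymous moves is degenerate

    n_states = len(pi)
    states = {tree.root: rng.choice(n_states, size=spec.n_codons, p=pi)}
    for node, parent, edge in tree.preorder:
        t = tree.branch_lengths[edge]
        child = np.empty(spec.n_codons, dtype=int)
        for om in distinct:
            mask = site_omega == om
            if not mask.any():
                continue
            P = decompose(Qs[om] / scale, pi).transition_matrix(t)
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            rows = cum[states[parent][mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = child

    codons = np.array(st.codons)
    seqs = []
    for i, taxon in enumerate(tree.taxa):
        seqs.append("".join(codons[states[i]]))
    aln = CodonAlignment(taxa=tree.taxa, sequences=tuple(seqs), code=spec.code)
    truth = {
        "seed": spec.seed, "site_omega": site_omega.tolist(),
        "kappa": spec.kappa, "scale": scale,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# negative-path fixtures

def perturb_annotation(
    record: MitogenomeRecord,
    modes: list[str],
    out_path: str | Path,
    seed: int = 0,
) -> tuple[Path, dict]:
    """Write a deliberately defective GenBank file for error-path tests.

    Modes: ``missing_origin`` (drop the ORIGIN block), ``internal_stop``
    (mutate a codon inside the first L-strand PCG to TAA),
    ``overlap`` (shift a tRNA start left by 10 onto its neighbour).
    An empty mode list writes the record unchanged.
    """
    out_path = Path(out_path)
    rec = MitogenomeRecord(
        accession=record.accession, length=record.length,
        sequence=record.sequence,
        features=[GeneFeature(**{
            "name": f.name, "element_class": f.element_class,
            "strand": f.strand, "start": f.start, "end": f.end,
            "anticodon": f.anticodon, "wraps": f.wraps,
        }) for f in record.features],
        circular=record.circular,
    )
    truth: dict = {"modes": list(modes)}
    if "internal_stop" in modes:
        pcg = next(
            f for f in rec.features
            if f.element_class == "PCG" and f.strand == "L"
        )
        codon_start = pcg.start - 1 + 3 * (pcg.size() // 6)  # mid-gene, in frame
        s = rec.sequence
        rec.sequence = s[:codon_start] + "TAA" + s[codon_start + 3:]
        truth["internal_stop"] = {"gene": pcg.name, "position": codon_start + 1}
    if "overlap" in modes:
        trna = next(f for f in rec.features if f.element_class == "tRNA")
        old = trna.start
        trna.start = max(1, trna.start - 10)
        truth["overlap"] = {"feature": trna.name, "old_start": old,
                            "new_start": trna.start}
        rec.features.sort(key=lambda f: (f.start, f.end))
    write_genbank(rec, out_path)
    if "missing_origin" in modes:
        lines = out_path.read_text().splitlines()
        kept = []
        skipping = False
        for ln in lines:
            if ln.startswith("ORIGIN"):
                skipping = True
                continue
            if skipping and ln.startswith("//"):
                skipping = False
            if not skipping:
                kept.append(ln)
        out_path.write_text("\n".join(kept) + "\n")
        truth["missing_origin"] = True
    return out_path, truth
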