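"""Concatenated phylogenetic datasets with partition maps.

Five standard supermatrix schemes combine the mitochondrial element
classes: PRT (PCGs + rRNAs + tRNAs), PR, PT, RT and P.  Blocks arrive
already aligned (alignment itself is upstream of this toolkit); a
transparent two-threshold column trimmer stands in for heavier
ambiguity filtering.  Partition maps always tile the supermatrix
exactly and every export asserts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

SCHEMES = {
    "PRT": ("PCG", "rRNA", "tRNA"),
    "PR": ("PCG", "rRNA"),
    "PT": ("PCG", "tRNA"),
    "RT": ("rRNA", "tRNA"),
    "P": ("PCG",),
}

_CLASS_ORDER = {"PCG": 0, "rRNA": 1, "tRNA": 2}


@dataclass
class AlignedBlock:
    name: str
    element_class: str  # PCG | rRNA | tRNA
    taxa: tuple[str, ...]
    columns: tuple[str, ...]  # aligned sequences, one per taxon
    #: original column indices (0-based) retained by trimming
    provenance: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.columns):
            raise ValueError(f"{self.name}: taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.name}: duplicate taxa")
        if len({len(s) for s in self.columns}) > 1:
            raise ValueError(f"{self.name}: unequal aligned lengths")

    @property
    def length(self) -> int:
        return len(self.columns[0])

    def sequence_of(self, taxon: str) -> str:
        return self.columns[self.taxa.index(taxon)]


@dataclass
class PartitionedSupermatrix:
    taxa: tuple[str, ...]
    sequences: dict[str, str]
    #: ordered (name, start, end), 1-based inclusive supermatrix coords
    partitions: list[tuple[str, int, int]]
    scheme: str

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def assert_tiling(self) -> None:
        """Partitions must tile [1, L] without gaps or overlaps."""
        expect = 1
        for name, start, end in self.partitions:
            if start != expect or end < start:
                raise AssertionError(
                    f"partition {name} at {start}-{end} breaks the tiling "
                    f"(expected start {expect})"
                )
            expect = end + 1
        if expect != self.length + 1:
            raise AssertionError(
                f"partitions cover {expect - 1} of {self.length} columns"
            )


def trim_ambiguous(
    block: AlignedBlock,
    max_gap_fraction: float = 0.5,
    min_conserved_fraction: float = 0.5,
) -> AlignedBlock:
    """Drop gappy and poorly conserved columns.

    A column is removed when its gap fraction exceeds `max_gap_fraction`
    or its majority-residue fraction (among non-gap characters) falls
    below `min_conserved_fraction`.  Retained original column indices are
    kept as provenance, which makes the filter idempotent.
    """
    n = len(block.taxa)
    keep: list[int] = []
    for j in range(block.length):
        col = [s[j] for s in block.columns]
        gaps = sum(1 for ch in col if ch == "-")
        if gaps / n > max_gap_fraction:
            continue
        residues = [ch for ch in col if ch != "-"]
        if residues:
            top = max(residues.count(ch) for ch in set(residues))
            if top / len(residues) < min_conserved_fraction:
                continue
        keep.append(j)
    if not keep:
        raise ValueError(f"{block.name}: trimming removed every column")
    prov = block.provenance or tuple(range(block.length))
    return AlignedBlock(
        name=block.name,
        element_class=block.element_class,
        taxa=block.taxa,
        columns=tuple("".join(s[j] for j in keep) for s in block.columns),
        provenance=tuple(prov[j] for j in keep),
    )


def concatenate(
    blocks: list[AlignedBlock],
    scheme: str = "PRT",
    taxa_order: list[str] | None = None,
) -> PartitionedSupermatrix:
    """Build a partitioned supermatrix for one scheme.

    Blocks are filtered by the scheme's element classes and ordered
    PCGs (input order), then rRNAs, then tRNAs.  Every selected block
    must contain every requested taxon — a missing taxon is a hard
    error, not silent gap padding.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected {sorted(SCHEMES)}")
    classes = SCHEMES[scheme]
    chosen = [b for b in blocks if b.element_class in classes]
    chosen.sort(key=lambda b: _CLASS_ORDER[b.element_class])
    if not chosen:
        raise ValueError(f"no blocks of classes {classes}")
    if taxa_order is None:
        taxa_order = list(chosen[0].taxa)
    for b in chosen:
        for t in taxa_order:
            if t not in b.taxa:
                raise ValueError(f"taxon {t!r} missing from block {b.name!r}")
    seqs = {t: [] for t in taxa_order}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for b in chosen:
        for t in taxa_order:
            seqs[t].append(b.sequence_of(t))
        partitions.append((b.name, pos, pos + b.length - 1))
        pos += b.length
    sm = PartitionedSupermatrix(
        taxa=tuple(taxa_order),
        sequences={t: "".join(parts) for t, parts in seqs.items()},
        partitions=partitions,
        scheme=scheme,
    )
    sm.assert_tiling()
    return sm


def export_supermatrix(
    sm: PartitionedSupermatrix, out_dir: str | Path, stem: str | None = None
) -> dict[str, Path]:
    """Write FASTA, relaxed PHYLIP, NEXUS (+charsets) and a RAxML-style
    partition file; returns the paths keyed by format."""
    sm.assert_tiling()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"supermatrix_{sm.scheme}"
    L = sm.length
    paths: dict[str, Path] = {}

    fasta = out_dir / f"{stem}.fasta"
    with open(fasta, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.sequences[t]}\n")
    paths["fasta"] = fasta

    phylip = out_dir / f"{stem}.phy"
    with open(phylip, "w") as fh:
        fh.write(f"{len(sm.taxa)} {L}\n")
        for t in sm.taxa:
            fh.write(f"{t.replace(' ', '_')}  {sm.sequences[t]}\n")
    paths["phylip"] = phylip

    nexus = out_dir / f"{stem}.nex"
    with open(nexus, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={L};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {t.replace(' ', '_')}  {sm.sequences[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for name, start, end in sm.partitions:
            fh.write(f"  CHARSET {name.replace(' ', '_')} = {start}-{end};\n")
        fh.write("END;\n")
    paths["nexus"] = nexus

    part = out_dir / f"{stem}.partitions"
    with open(part, "w") as fh:
        for name, start, end in sm.partitions:
            fh.write(f"DNA, {name.replace(' ', '_')} = {start}-{end}\n")
    paths["raxml"] = part
    return paths


def blocks_from_record(record, gene_names: list[str] | None = None) -> list[AlignedBlock]:
    """Single-taxon blocks from one annotated genome (a convenience for
    assembling multi-genome blocks feature-by-feature)."""
    from .mito_io import feature_sequence

    out = []
    for f in record.features:
        if f.element_class not in _CLASS_ORDER:
            continue
        if gene_names is not None and f.name not in gene_names:
            continue
        out.append(
            AlignedBlock(
                name=f.name, element_class=f.element_class,
                taxa=(record.accession,),
                columns=(feature_sequence(record, f),),
            )
        )
    return out
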