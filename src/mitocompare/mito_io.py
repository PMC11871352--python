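"""Annotated mitogenome I/O and the genome feature table.

A :class:`MitogenomeRecord` is a circular annotated genome: the sequence
as deposited (the reference strand, labelled L following the source
annotations) plus an ordered list of features.  The feature table mirrors
the standard comparative-mitogenomics summary: per element its size,
the intergenic spacer to the preceding element (negative = overlap),
A+T percentage and, for protein-coding genes, start/stop codons with
incomplete stops written ``T--`` / ``TA-``.

Coordinates are 1-based inclusive throughout (GenBank convention).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genetic_code import VERTEBRATE_MITO, GeneticCode

ELEMENT_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

#: Normalization of common annotation spellings to the gene symbols used
#: in the feature table. Unknown names pass through unchanged.
GENE_NAME_MAP = {
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND4L": "nad4L", "ND5": "nad5", "ND6": "nad6",
    "NAD1": "nad1", "NAD2": "nad2", "NAD3": "nad3", "NAD4": "nad4",
    "NAD4L": "nad4L", "NAD5": "nad5", "NAD6": "nad6",
    "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
    "COI": "cox1", "COII": "cox2", "COIII": "cox3",
    "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
    "CYTB": "cytb", "COB": "cytb", "MT-CYB": "cytb",
    "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
    "12S": "12S-rRNA", "RRNS": "12S-rRNA", "S-RRNA": "12S-rRNA",
    "12S RIBOSOMAL RNA": "12S-rRNA", "12S RRNA": "12S-rRNA",
    "16S": "16S-rRNA", "RRNL": "16S-rRNA", "L-RRNA": "16S-rRNA",
    "16S RIBOSOMAL RNA": "16S-rRNA", "16S RRNA": "16S-rRNA",
    "D-LOOP": "control_region", "CONTROL REGION": "control_region",
}

_AA3_TO_TRNA = {
    "Ala": "tRNA-Ala", "Arg": "tRNA-Arg", "Asn": "tRNA-Asn", "Asp": "tRNA-Asp",
    "Cys": "tRNA-Cys", "Gln": "tRNA-Gln", "Glu": "tRNA-Glu", "Gly": "tRNA-Gly",
    "His": "tRNA-His", "Ile": "tRNA-Ile", "Leu": "tRNA-Leu", "Lys": "tRNA-Lys",
    "Met": "tRNA-Met", "Phe": "tRNA-Phe", "Pro": "tRNA-Pro", "Ser": "tRNA-Ser",
    "Thr": "tRNA-Thr", "Trp": "tRNA-Trp", "Tyr": "tRNA-Tyr", "Val": "tRNA-Val",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

INCOMPLETE_STOPS = ("T--", "TA-")


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated mitochondrial element on the reference strand."""

    name: str
    element_class: str
    strand: str  # 'L' or 'H' as annotated
    start: int  # 1-based inclusive
    end: int
    anticodon: str | None = None
    wraps: bool = False  # spans the circular origin (start > end)
    start_codon: str | None = None  # annotation-supplied, PCGs only
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.strand not in ("L", "H"):
            raise ValueError(f"strand must be 'L' or 'H', got {self.strand!r}")
        if self.start > self.end and not self.wraps:
            raise ValueError(
                f"{self.name}: start {self.start} > end {self.end} on a "
                "non-wrapping feature"
            )

    def size(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("genome length needed for a wrapping feature")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """A circular annotated mitogenome on its deposited reference strand."""

    accession: str
    length: int
    features: list[GeneFeature]
    sequence: str | None = None  # None for coordinate-only (printed) tables
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"length field {self.length} != sequence length "
                f"{len(self.sequence)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise ValueError(
                    f"feature {f.name} at {f.start}..{f.end} outside "
                    f"[1, {self.length}]"
                )

    def features_of_class(self, element_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.element_class == element_class]

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class FeatureRow:
    """One feature-table row (the per-element summary)."""

    feature: GeneFeature
    size: int
    intergenic: int
    at_percent: float | None
    start_codon: str | None
    stop_codon: str | None


def normalize_gene_name(raw: str) -> str:
    return GENE_NAME_MAP.get(raw.strip().upper(), raw.strip())


def _feature_name(feat: SeqFeature) -> str:
    q = feat.qualifiers
    for key in ("gene", "product", "note"):
        if key in q and q[key]:
            return str(q[key][0])
    return feat.type


def _trna_name(raw: str) -> tuple[str, str | None]:
    """Map 'tRNA-Gly' / 'trnG-ucc' style names; returns (name, anticodon)."""
    s = raw.strip()
    for aa3, name in _AA3_TO_TRNA.items():
        if aa3.lower() in s.lower():
            return name, None
    return s, None


def read_genbank(path: str | Path, code: GeneticCode = VERTEBRATE_MITO) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    CDS features become PCGs, tRNA/rRNA keep their class, and the control
    region is recognized from D-loop features or misc_features whose note
    mentions the control region.  Duplicate gene/CDS pairs covering the
    same span are collapsed to one feature.
    """
    path = Path(path)
    text = path.read_text()
    if "ORIGIN" not in text:
        raise GenBankParseError(f"{path}: no ORIGIN sequence block")
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise GenBankParseError(f"{path}: {exc}") from exc
    if len(rec.seq) == 0:
        raise GenBankParseError(f"{path}: empty ORIGIN sequence")

    feats: list[GeneFeature] = []
    seen_spans: set[tuple[int, int, str]] = set()
    for feat in rec.features:
        if feat.type == "CDS":
            element_class = "PCG"
            name = normalize_gene_name(_feature_name(feat))
            anticodon = None
        elif feat.type == "tRNA":
            element_class = "tRNA"
            name, anticodon = _trna_name(_feature_name(feat))
            ac = feat.qualifiers.get("anticodon")
            if ac:
                anticodon = str(ac[0]).strip("()").split(":")[-1].strip(") ").upper() or None
                if anticodon:
                    anticodon = anticodon.replace("T", "U")
        elif feat.type == "rRNA":
            element_class = "rRNA"
            name = normalize_gene_name(_feature_name(feat))
            anticodon = None
        elif feat.type == "D-loop" or (
            feat.type == "misc_feature"
            and "control" in " ".join(
                feat.qualifiers.get("note", [])
            ).lower()
        ):
            element_class = "CR"
            name = "control_region"
            anticodon = None
        else:
            continue

        loc = feat.location
        start = int(loc.start) + 1  # Biopython is 0-based half-open
        end = int(loc.end)
        wraps = False
        if hasattr(loc, "parts") and len(loc.parts) > 1:
            # join(x..L,1..y) — origin-spanning feature
            p0, p1 = loc.parts[0], loc.parts[-1]
            start, end, wraps = int(p0.start) + 1, int(p1.end), True
        strand = "L" if (loc.strand or 1) >= 0 else "H"
        key = (start, end, element_class)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        feats.append(
            GeneFeature(
                name=name, element_class=element_class, strand=strand,
                start=start, end=end, anticodon=anticodon, wraps=wraps,
            )
        )

    topology = rec.annotations.get("topology", "circular")
    return MitogenomeRecord(
        accession=rec.id or rec.name,
        length=len(rec.seq),
        sequence=str(rec.seq).upper(),
        features=feats,
        circular=(topology != "linear"),
    )


def feature_sequence(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature.

    L-strand features (matching the deposited orientation) are a direct
    slice; H-strand features are reverse-complemented.  Origin-spanning
    features are stitched across the circular junction.
    """
    if record.sequence is None:
        raise ValueError("record carries no sequence")
    if feature.wraps:
        if not record.circular:
            raise ValueError(
                f"{feature.name} wraps the origin of a linear record"
            )
        raw = record.sequence[feature.start - 1:] + record.sequence[: feature.end]
    else:
        raw = record.sequence[feature.start - 1: feature.end]
    return raw if feature.strand == "L" else reverse_complement(raw)


def _observed_codons(cds: str, size: int) -> tuple[str, str]:
    """Start and stop codon strings, with incomplete stops as T--/TA-."""
    start = cds[:3]
    rem = size % 3
    if rem == 0:
        stop = cds[-3:]
    elif rem == 1:
        stop = cds[-1] + "--"
    else:
        stop = cds[-2:] + "-"
    return start, stop


def build_feature_table(
    record: MitogenomeRecord, code: GeneticCode = VERTEBRATE_MITO
) -> list[FeatureRow]:
    """Per-element summary rows in genome order.

    ``intergenic`` of row *i* is ``start(i) − end(i−1) − 1`` (negative for
    overlaps); the first row is 0 by convention — the junction that wraps
    the origin back to the first feature is not counted.  For records
    without sequence (coordinate-only tables) codons come from the
    annotation and AT% is None.
    """
    from .composition import base_composition  # local import, avoids cycle

    if not record.features:
        raise ValueError("record has no features")
    rows: list[FeatureRow] = []
    prev_end: int | None = None
    for feat in record.features:
        size = feat.size(record.length)
        intergenic = 0 if prev_end is None else feat.start - prev_end - 1
        prev_end = feat.end if not feat.wraps else feat.end  # wrap end is past origin
        at_percent = None
        start_codon = feat.start_codon
        stop_codon = feat.stop_codon
        if record.sequence is not None:
            seq = feature_sequence(record, feat)
            at_percent = base_composition(seq).at_percent
            if feat.element_class == "PCG":
                start_codon, stop_codon = _observed_codons(seq, size)
                limit = size - (3 if size % 3 == 0 else size % 3)
                for i in range(3, limit, 3):
                    codon = seq[i: i + 3]
                    if code.is_stop(codon):
                        warnings.warn(
                            f"{feat.name}: internal stop codon {codon} at "
                            f"coding position {i + 1}",
                            stacklevel=2,
                        )
                        break
        elif feat.element_class == "PCG" and stop_codon is None and size % 3:
            stop_codon = "T--" if size % 3 == 1 else "TA-"
        rows.append(
            FeatureRow(
                feature=feat, size=size, intergenic=intergenic,
                at_percent=at_percent, start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
    return rows


def genome_length_from_table(rows: list[FeatureRow]) -> int:
    """Genome size implied by a feature table: the maximum end coordinate."""
    if not rows:
        raise ValueError("empty feature table")
    return max(r.feature.end for r in rows)


_TSV_COLUMNS = (
    "name", "element_class", "strand", "start", "end", "size", "intergenic",
    "at_percent", "start_codon", "stop_codon", "anticodon",
)


def write_feature_table(rows: list[FeatureRow], path: str | Path) -> None:
    """Write rows as TSV mirroring the per-element summary table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for r in rows:
            f = r.feature
            w.writerow([
                f.name, f.element_class, f.strand, f.start, f.end, r.size,
                r.intergenic,
                "" if r.at_percent is None else f"{r.at_percent:.6f}",
                r.start_codon or "", r.stop_codon or "", f.anticodon or "",
            ])


def read_feature_table(path: str | Path) -> list[FeatureRow]:
    """Reread a TSV written by :func:`write_feature_table` (lossless)."""
    rows: list[FeatureRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            feat = GeneFeature(
                name=rec["name"], element_class=rec["element_class"],
                strand=rec["strand"], start=int(rec["start"]),
                end=int(rec["end"]), anticodon=rec["anticodon"] or None,
                wraps=int(rec["start"]) > int(rec["end"]),
            )
            rows.append(
                FeatureRow(
                    feature=feat, size=int(rec["size"]),
                    intergenic=int(rec["intergenic"]),
                    at_percent=float(rec["at_percent"]) if rec["at_percent"] else None,
                    start_codon=rec["start_codon"] or None,
                    stop_codon=rec["stop_codon"] or None,
                )
            )
    return rows


def record_to_json(record: MitogenomeRecord, path: str | Path) -> None:
    payload = {
        "accession": record.accession,
        "length": record.length,
        "circular": record.circular,
        "sequence": record.sequence,
        "features": [
            {
                "name": f.name, "element_class": f.element_class,
                "strand": f.strand, "start": f.start, "end": f.end,
                "anticodon": f.anticodon, "wraps": f.wraps,
            }
            for f in record.features
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def export_feature_fasta(record: MitogenomeRecord, out_dir: str | Path) -> list[Path]:
    """Write each feature's coding-strand sequence as one FASTA file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, feat in enumerate(record.features, 1):
        seq = feature_sequence(record, feat)
        safe = feat.name.replace("/", "_").replace(" ", "_")
        p = out_dir / f"{i:02d}_{safe}.fasta"
        SeqIO.write(
            [SeqRecord(Seq(seq), id=f"{record.accession}|{feat.name}",
                       description=f"{feat.start}..{feat.end} {feat.strand}")],
            str(p), "fasta",
        )
        written.append(p)
    return written


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write a record (with sequence) as a GenBank flat file.

    The LOCUS date is pinned so identical records give identical bytes.
    """
    if record.sequence is None:
        raise ValueError("cannot write GenBank without sequence")
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description="synthetic mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "date": "01-JAN-2020",
            "data_file_division": "VRT",
        },
    )
    for f in record.features:
        strand = 1 if f.strand == "L" else -1
        loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}[
            f.element_class
        ]
        quals: dict[str, list[str]] = {}
        if f.element_class != "CR":
            quals["gene"] = [f.name]
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def load_printed_table(species: str) -> MitogenomeRecord:
    """Load a shipped coordinate-only table as a sequence-less record.

    ``species`` is ``"palea_steindachneri"`` or ``"pelodiscus_axenaria"``
    (the two deposited soft-shelled turtle mitogenomes whose printed
    coordinates ship with the package).
    """
    name = f"table1_{species}.tsv"
    ref = resources.files("mitocompare.data") / name
    lines = ref.read_text().splitlines()
    accession = lines[0].split("\t")[1]
    length = int(lines[1].split("\t")[1])
    feats = []
    reader = csv.DictReader(lines[2:], delimiter="\t")
    for rec in reader:
        feats.append(
            GeneFeature(
                name=rec["name"], element_class=rec["element_class"],
                strand=rec["strand"], start=int(rec["start"]),
                end=int(rec["end"]),
                anticodon=None if rec["anticodon"] == "." else rec["anticodon"],
                start_codon=None if rec["start_codon"] == "." else rec["start_codon"],
                stop_codon=None if rec["stop_codon"] == "." else rec["stop_codon"],
            )
        )
    return MitogenomeRecord(
        accession=accession, length=length, features=feats, sequence=None
    )
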