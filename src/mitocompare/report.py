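"""End-to-end comparative report over one or more annotated genomes."""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .codon_usage import (
    amino_acid_total_from_rows,
    at_gc_rich_ratio,
    count_codons,
    rscu,
)
from .composition import composition_profile
from .control_region import annotate_control_region
from .mito_io import (
    build_feature_table,
    feature_sequence,
    read_genbank,
    write_feature_table,
)


class ReportError(RuntimeError):
    """A stage failed; the bundle written so far is partial."""


def run_report(
    genbank_paths: list[str | Path],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Run features → composition → codons → control-region scan for each
    genome and write a JSON bundle plus per-genome TSVs.

    Selection analyses need per-gene alignments across many taxa and are
    reported as skipped unless the config provides them.
    """
    if not genbank_paths:
        raise ValueError("need at least one genome")
    config = config or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "tool": {"name": "mitocompare", "version": __version__},
        "config": {k: v for k, v in config.items() if k != "alignments"},
        "genomes": {},
        "selection": {"status": "skipped",
                      "reason": "no per-gene alignments provided"},
    }
    failures = []
    for p in genbank_paths:
        p = Path(p)
        try:
            record = read_genbank(p)
            rows = build_feature_table(record)
            write_feature_table(rows, out_dir / f"{record.accession}_features.tsv")
            prof = composition_profile(record)
            prof.to_csv(out_dir / f"{record.accession}_composition.tsv",
                        sep="\t", index=False)
            pcg_seqs = [
                feature_sequence(record, f)
                for f in record.features_of_class("PCG")
            ]
            codons = count_codons(pcg_seqs)
            cr = annotate_control_region(record)
            full = prof[(prof["kind"] == "full") & (prof["strand"] == "L")].iloc[0]
            bundle["genomes"][record.accession] = {
                "path": str(p),
                "length": record.length,
                "n_features": len(record.features),
                "feature_classes": {
                    c: len(record.features_of_class(c))
                    for c in ("PCG", "tRNA", "rRNA", "CR")
                },
                "amino_acids_encoded": amino_acid_total_from_rows(rows),
                "at_percent": float(full["at_percent"]),
                "at_skew": float(full["at_skew"]),
                "gc_skew": float(full["gc_skew"]),
                "at_gc_rich_ratio": at_gc_rich_ratio(codons),
                "top_codon": codons.top_codons()[0][0],
                "control_region": cr,
            }
        except Exception as exc:  # keep going, flag at exit
            failures.append((str(p), repr(exc)))
    if len(bundle["genomes"]) >= 2:
        accs = list(bundle["genomes"])
        a, b = accs[0], accs[1]
        cr_a = bundle["genomes"][a]["control_region"]["control_region"]["length"]
        cr_b = bundle["genomes"][b]["control_region"]["control_region"]["length"]
        bundle["comparison"] = {
            "accessions": accs,
            "genome_length_difference": abs(
                bundle["genomes"][a]["length"] - bundle["genomes"][b]["length"]
            ),
            "control_region_length_difference": abs(cr_a - cr_b),
        }
    bundle["failures"] = [{"path": p, "error": e} for p, e in failures]
    (out_dir / "report.json").write_text(json.dumps(bundle, indent=1))
    if failures:
        raise ReportError(
            f"{len(failures)} genome(s) failed; partial bundle written to "
            f"{out_dir}"
        )
    return bundle
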