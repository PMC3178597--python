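"""End-to-end orchestration: preprocess -> group -> align -> distances ->
trees -> per-species divergences -> locus comparison -> summary.

Every stage writes a plain-text artifact (TSV / gapped FASTA / Newick /
square PHYLIP) into the output directory, plus ``run_log.txt`` recording
parameters, seed, capping events, and UNDEFINED-distance events.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, barcode_gap, distance, grouping, io
from .pairwise import AlignmentParams


class ValidationFailure(Exception):
    """Bad inputs or configuration (CLI exit code 1)."""


class ComputationFailure(Exception):
    """A stage could not produce a result (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    fasta: dict[str, str] = field(default_factory=dict)  # locus -> FASTA path
    metadata: str = ""
    output_dir: str = "mycobarcode_out"
    min_identity: float = 0.80
    min_overlap: int = 100
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    cap_threshold: float = barcode_gap.CAP_THRESHOLD
    cap_value: float = barcode_gap.CAP_VALUE
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValidationFailure(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def grouping_params(self) -> grouping.GroupingParams:
        return grouping.GroupingParams(
            min_identity=self.min_identity,
            min_overlap=self.min_overlap,
            alignment=AlignmentParams(match=self.match, mismatch=self.mismatch,
                                      gap=self.gap, terminal_gaps_free=True),
        )


def _write_rows_tsv(rows, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tlocus\tn\tintra_max\tintra_mean\tintra_median\t"
                 "inter_min\tnearest_neighbor\n")
        for r in rows:
            def fmt(v):
                return "NA" if v is None else f"{v:.4f}"
            inter = f">{barcode_gap.CAP_THRESHOLD:.2f}" if r.inter_capped else f"{r.inter_min:.4f}"
            fh.write(f"{r.species}\t{r.locus}\t{r.n}\t{fmt(r.intra_max)}\t"
                     f"{fmt(r.intra_mean)}\t{fmt(r.intra_median)}\t{inter}\t"
                     f"{r.nearest_neighbor or 'NONE'}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory results keyed by stage."""
    log_lines: list[str] = [
        f"mycobarcode {__version__}",
        f"seed={config.seed} min_identity={config.min_identity} "
        f"min_overlap={config.min_overlap} cap={config.cap_value}@>{config.cap_threshold}",
    ]
    if not config.fasta:
        raise ValidationFailure("no FASTA inputs configured")
    if not config.metadata:
        raise ValidationFailure("no metadata file configured")
    meta_path = Path(config.metadata)
    if not meta_path.exists():
        raise ValidationFailure(f"metadata file not found: {meta_path}")
    try:
        metadata = io.read_metadata(meta_path)
    except io.FormatError as exc:
        raise ValidationFailure(str(exc)) from exc
    labels = io.species_labels(metadata)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gparams = config.grouping_params()
    results: dict = {"rows": {}, "groups": {}, "summary": {}}

    for locus, fasta_path in sorted(config.fasta.items()):
        if not Path(fasta_path).exists():
            raise ValidationFailure(f"FASTA file not found: {fasta_path}")
        try:
            records = io.read_fasta(fasta_path, locus=locus)
        except io.FormatError as exc:
            raise ValidationFailure(str(exc)) from exc
        missing = [r.id for r in records if r.id not in labels]
        if missing:
            raise ValidationFailure(
                f"{locus}: sequences missing from metadata: {missing[:5]}"
            )
        groups = grouping.build_groups(records, gparams)
        results["groups"][locus] = groups
        with open(out / f"{locus}_groups.tsv", "w") as fh:
            fh.write("group_id\tsequence_id\tjoin_identity\toverlap_len\n")
            for g in groups:
                for rid in g.member_ids:
                    ident, olen = g.join_stats.get(rid, (float("nan"), 0))
                    fh.write(f"{g.group_id}\t{rid}\t{ident:.4f}\t{olen}\n")
        for g in groups:
            if g.msa is not None:
                io.write_fasta(g.msa, out / f"{locus}_{g.group_id}_msa.fasta")
                matrix = distance.matrix_from_msa(g.msa)
                io.write_phylip(matrix, out / f"{locus}_{g.group_id}.phylip")
                for pair in matrix.undefined_pairs:
                    log_lines.append(f"UNDEFINED distance: {locus} {g.group_id} {pair}")
                if len(g.members) >= 3 and not matrix.has_undefined:
                    tree = distance.nj_tree(matrix)
                    io.write_newick(tree, out / f"{locus}_{g.group_id}.nwk")
        try:
            rows = barcode_gap.species_stats(
                groups, labels, locus,
                cap_threshold=config.cap_threshold, cap_value=config.cap_value,
            )
        except barcode_gap.BarcodeGapError as exc:
            raise ComputationFailure(str(exc)) from exc
        for r in rows:
            if r.inter_capped:
                log_lines.append(f"CAPPED inter_min: {locus} {r.species}")
        results["rows"][locus] = rows
        _write_rows_tsv(rows, out / f"{locus}_species_divergences.tsv")
        summary = barcode_gap.summary_report(rows)
        results["summary"][locus] = summary
        with open(out / f"{locus}_summary.tsv", "w") as fh:
            fh.write("locus\tn_species\tintra_max\tintra_mean\tintra_se\tintra_median\t"
                     "inter_min\tinter_mean\tinter_se\tinter_median\tn_capped\n")
            def fmt(v):
                return "NA" if v is None else f"{v:.4f}"
            fh.write("\t".join([
                summary.locus, str(summary.n_species), fmt(summary.intra_max),
                fmt(summary.intra_mean), fmt(summary.intra_se), fmt(summary.intra_median),
                fmt(summary.inter_min), fmt(summary.inter_mean), fmt(summary.inter_se),
                fmt(summary.inter_median), str(summary.n_capped),
            ]) + "\n")

    if {"COI", "ITS"} <= set(results["rows"]):
        comparisons = barcode_gap.compare_loci(results["rows"]["COI"],
                                               results["rows"]["ITS"])
        results["comparisons"] = comparisons
        with open(out / "locus_comparison.tsv", "w") as fh:
            fh.write("species\tcoi_ratio\tits_ratio\tbetter_locus\n")
            for c in comparisons:
                fh.write(f"{c.species}\t{c.coi_ratio:.4f}\t{c.its_ratio:.4f}\t{c.better_locus}\n")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    config.to_yaml(out / "config_used.yaml")
    return results


def main_pipeline(config: PipelineConfig) -> int:
    """Run the pipeline with the CLI's exit-code contract."""
    try:
        run_pipeline(config)
    except ValidationFailure as exc:
        print(f"validation error: {exc}", file=sys.stderr)
        return 1
    except (ComputationFailure, distance.DistanceError) as exc:
        print(f"computation error: {exc}", file=sys.stderr)
        return 2
    return 0
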