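"""End-to-end orchestration: ROH mapping -> variant filter -> coverage
screen -> deletion annotation, behind a validated flat config.

The discovery report aggregates every stage's output with provenance
(config hash, seed, package version); regenerating it from the same inputs
is byte-identical.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .coverage_screen import (
    CoverageParams,
    build_depth_table,
    call_deletions,
    compare_to_panel,
    exon_mean_depth,
    model_exon_frame,
    read_depth_track,
)
from .deletion_annotation import (
    PrimerPair,
    annotate_deletion,
    classify_pcr_genotype,
    in_silico_pcr,
    parse_hgvs_c_del,
)
from .gene_model import GenomeSequence, load_transcript
from .roh_mapping import (
    GenotypeMatrix,
    RohParams,
    detect_roh,
    intersect_shared,
)
from .synthetic_data import apply_deletion
from .variant_filter import run_cascade

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """One or more config problems, all collected before failing."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _interval(text: str) -> tuple[int, int]:
    lo, hi = (int(x) for x in text.split("-"))
    return lo, hi


# key -> (type, default, is_path, validator). Required keys have default None.
_SCHEMA: dict[str, tuple] = {
    "genotypes": (str, None, True, None),
    "vcf": (str, None, True, None),
    "model": (str, None, True, None),
    "genome": (str, None, True, None),
    "depth_case": (str, None, True, None),
    "depth_panel": (str, None, True, None),  # comma-separated paths
    "affected": (str, None, False, None),  # comma-separated sample ids
    "case_sample": (str, None, False, None),
    "transcript_id": (str, "TOYTX1", False, None),
    "out_dir": (str, "homdel_out", False, None),
    "seed": (int, 0, False, lambda v: v >= 0),
    "roh_min_markers": (int, 25, False, lambda v: v >= 1),
    "roh_min_length_bp": (int, 1_000_000, False, lambda v: v >= 0),
    "roh_max_het": (int, 1, False, lambda v: v >= 0),
    "roh_max_missing": (int, 2, False, lambda v: v >= 0),
    "filter_unit_max": (int, 6, False, lambda v: v >= 1),
    "filter_min_copies": (int, 4, False, lambda v: v >= 2),
    "cov_max_ratio": (float, 0.1, False, lambda v: 0 <= v <= 1),
    "cov_min_panel_depth": (float, 10.0, False, lambda v: v >= 0),
    "cov_normalize": (bool, False, False, None),
    "annot_hgvs_del": (str, "", False, None),
    "annot_normalize_3prime": (bool, False, False, None),
    "pcr_longrange_forward": (str, "", False, None),  # "start-end"
    "pcr_longrange_reverse": (str, "", False, None),
    "pcr_exon_forward": (str, "", False, None),
    "pcr_exon_reverse": (str, "", False, None),
}
_REQUIRED = [k for k, (_, d, _, _) in _SCHEMA.items() if d is None]


@dataclass
class RunConfig:
    values: dict

    def __getattr__(self, key):
        try:
            return self.__dict__["values"][key]
        except KeyError as exc:
            raise AttributeError(key) from exc

    def hash(self) -> str:
        payload = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_config(cfg_file: str | Path) -> RunConfig:
    """Parse and validate a flat key-value YAML config.

    All problems (types, ranges, unknown keys with suggestions, missing
    files) are collected and reported together.
    """
    try:
        raw = yaml.safe_load(Path(cfg_file).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot read config: {exc}"])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a flat key-value mapping"])

    errors: list[str] = []
    values: dict = {}
    for key, value in raw.items():
        if key not in _SCHEMA:
            hint = difflib.get_close_matches(key, _SCHEMA, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
            continue
        typ, _default, _is_path, validator = _SCHEMA[key]
        try:
            if typ is bool and isinstance(value, str):
                value = value.lower() in {"1", "true", "yes"}
            value = typ(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: expected {typ.__name__}, got {value!r}")
            continue
        if validator is not None and not validator(value):
            errors.append(f"{key}: value {value!r} out of range")
            continue
        values[key] = value

    for key, (typ, default, is_path, _v) in _SCHEMA.items():
        if key in values:
            continue
        if default is None:
            errors.append(f"missing required key {key!r}")
        else:
            values[key] = default

    for key, (_t, _d, is_path, _v) in _SCHEMA.items():
        if not is_path or key not in values:
            continue
        paths = values[key].split(",") if key == "depth_panel" else [values[key]]
        for p in paths:
            if p and not Path(p).exists():
                errors.append(f"{key}: path {p!r} does not exist")

    if errors:
        raise ConfigError(errors)
    return RunConfig(values=values)


@dataclass
class DiscoveryReport:
    shared_regions: list[dict]
    cascade_counts: list[dict]
    cascade_survivors: list[dict]
    deletion_calls: list[dict]
    consequence: dict | None
    genotype_classifications: dict
    provenance: dict
    candidate_found: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = ["# discovery report"]
        lines.append(f"shared regions: {len(self.shared_regions)}")
        for r in self.shared_regions:
            lines.append(
                f"  {r['chrom']}:{r['start']}-{r['end']} ({r['size_mb']} Mb, "
                f"{r['n_markers']} markers)"
            )
        lines.append("variant cascade:")
        for st in self.cascade_counts:
            lines.append(f"  {st['stage']}: {st['n_in']} -> {st['n_out']}")
        cands = [
            c for c in self.deletion_calls
            if c["verdict"] == "homozygous_deletion_candidate"
        ]
        lines.append(f"homozygous-deletion candidate exons: {len(cands)}")
        for c in cands:
            lines.append(
                f"  {c['gene']} exon {c['exon_index']} "
                f"({c['case_depth']} vs panel {c['panel_mean']} reads/base)"
            )
        if self.consequence:
            q = self.consequence
            lines.append(
                f"deletion {q['hgvs_c']}: {q['total_length']} bp "
                f"({q['coding_bases_removed']} coding + "
                f"{q['intronic_bases_removed']} intronic), "
                f"{'in-frame' if q['in_frame'] else 'frameshift'}, "
                f"{q['protein_hgvs']}, protein {q['wt_protein_length']} -> "
                f"{q['mut_protein_length']} aa"
            )
        if self.genotype_classifications:
            lines.append("in-silico PCR genotype classes:")
            for k, v in sorted(self.genotype_classifications.items()):
                lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


def run_discovery(cfg: RunConfig) -> DiscoveryReport:
    """Run all four analysis stages and aggregate the report.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    produced so far are retained in ``out_dir`` next to a FAILED marker.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                failed_marker.write_text(f"{name}: {exc}\n")
                raise StageError(name, str(exc)) from exc

        return wrap

    # 1. shared autozygosity
    def roh_stage():
        matrix = GenotypeMatrix.from_tsv(cfg.genotypes)
        params = RohParams(
            min_markers=cfg.roh_min_markers,
            min_length_bp=cfg.roh_min_length_bp,
            max_het=cfg.roh_max_het,
            max_missing=cfg.roh_max_missing,
        )
        affected = [s.strip() for s in cfg.affected.split(",") if s.strip()]
        per_sample = [detect_roh(matrix, s, params) for s in affected]
        return intersect_shared(per_sample, genotypes=matrix)

    shared = _stage("roh")(roh_stage)
    logger.info("shared regions: %d", len(shared))

    genome = _stage("inputs")(lambda: GenomeSequence.from_fasta(cfg.genome))
    model = _stage("inputs")(
        lambda: load_transcript(cfg.model, cfg.transcript_id)
    )

    # 2. variant filter cascade
    def filter_stage():
        return run_cascade(
            cfg.vcf,
            shared,
            genome=genome,
            unit_max=cfg.filter_unit_max,
            min_copies=cfg.filter_min_copies,
        )

    report = _stage("filter")(filter_stage)
    logger.info("cascade: %s", report.summary())

    # 3. coverage screen
    def coverage_stage():
        exons = model_exon_frame(model)
        panel_paths = [p for p in cfg.depth_panel.split(",") if p]
        columns = {cfg.case_sample: exon_mean_depth(
            read_depth_track(cfg.depth_case), exons
        )}
        panel_names = []
        for i, p in enumerate(panel_paths, start=1):
            name = f"panel_{i}"
            panel_names.append(name)
            columns[name] = exon_mean_depth(read_depth_track(p), exons)
        table = build_depth_table(exons, columns)
        table = compare_to_panel(
            table, cfg.case_sample, panel_names, normalize=cfg.cov_normalize
        )
        return call_deletions(
            table,
            CoverageParams(
                max_ratio=cfg.cov_max_ratio,
                min_panel_depth=cfg.cov_min_panel_depth,
            ),
        )

    calls = _stage("coverage")(coverage_stage)

    # 4. deletion annotation + diagnostic PCR
    consequence = None
    genotype_classes: dict[str, str] = {}

    def annotation_stage():
        nonlocal consequence, genotype_classes
        if not cfg.annot_hgvs_del:
            return
        desc = parse_hgvs_c_del(cfg.annot_hgvs_del, model)
        cons = annotate_deletion(
            desc, model, genome, normalize_3prime=cfg.annot_normalize_3prime
        )
        consequence = asdict(cons)
        if cfg.pcr_longrange_forward and cfg.pcr_exon_forward:
            longrange = PrimerPair(
                model.chrom,
                _interval(cfg.pcr_longrange_forward),
                _interval(cfg.pcr_longrange_reverse),
                label="longrange",
            )
            exon_internal = PrimerPair(
                model.chrom,
                _interval(cfg.pcr_exon_forward),
                _interval(cfg.pcr_exon_reverse),
                label="exon_internal",
            )
            wt, mut = genome, apply_deletion(
                genome, cons.chrom, cons.genomic_start, cons.genomic_end
            )
            for label, alleles in (
                ("wild_type_alleles", (wt, wt)),
                ("carrier_alleles", (wt, mut)),
                ("deleted_alleles", (mut, mut)),
            ):
                e6 = [in_silico_pcr(a, exon_internal) for a in alleles]
                lr = [in_silico_pcr(a, longrange) for a in alleles]
                genotype_classes[label] = classify_pcr_genotype(e6, lr)

    _stage("annotation")(annotation_stage)

    candidates = [c for c in calls if c.verdict == "homozygous_deletion_candidate"]
    discovery = DiscoveryReport(
        shared_regions=[
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "size_mb": r.size_mb,
                "n_markers": r.n_markers,
            }
            for r in shared
        ],
        cascade_counts=[
            {"stage": s.name, "n_in": s.n_in, "n_out": s.n_out}
            for s in report.stages
        ],
        cascade_survivors=[
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "functional_class": v.functional_class,
                "flags": v.flags,
            }
            for v in report.survivors
        ],
        deletion_calls=[asdict(c) for c in calls],
        consequence=consequence,
        genotype_classifications=genotype_classes,
        provenance={
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "version": __version__,
        },
        candidate_found=bool(candidates),
    )
    if failed_marker.exists():
        failed_marker.unlink()
    (out_dir / "report.json").write_text(discovery.to_json())
    (out_dir / "report.txt").write_text(discovery.to_text())
    return discovery
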