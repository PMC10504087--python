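"""End-to-end orchestration: config validation, stage running, escape report.

A pipeline run takes a YAML/JSON config naming either a preset synthetic
scenario or on-disk inputs (CN matrices + locus BED), executes the stages in
dependency order — per-cell locus CN states, clone decomposition and
event-parsimony tree, fish-plot table, bulk variant CCFs, per-gene biallelic
status, convergence detection — and writes every stage artifact plus a
combined per-gene escape report and a manifest under the output directory.
Given the same config and seed the outputs are byte-identical.

Subclone fractions for CN-defined events (focal biallelic deletions,
translocation disruptions) are taken as given inputs to the convergence
stage, mirroring how such fractions arrive from bulk WGS/SV analysis rather
than from read phasing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import bulk_inference as bi
from . import clonal_phylogeny as cp
from . import cn_state as cs
from . import convergence as cv
from . import genomic_core as gc
from . import synthetic_cohort as sc

log = logging.getLogger("mmescape")

TIMEPOINTS = ("pre", "post")

_SCENARIO_LOCI = {
    "MM1-like": [sc.TNFRSF17_LOCUS],
    "MM2-like": [sc.TNFRSF17_LOCUS],
    "MM31-like": [sc.GPRC5D_LOCUS],
    "MM32-like": [sc.GPRC5D_LOCUS],
    "null-diploid": [sc.TNFRSF17_LOCUS, sc.GPRC5D_LOCUS],
}


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    output_dir: Path
    seed: int = 0
    scenario: str | None = None
    cn_matrix_paths: dict[str, Path] = field(default_factory=dict)
    loci_bed: Path | None = None
    noise_free: bool = False
    # calibrated so a 9-bin focal event on the 250-bin preset genome
    # (distance 0.036 CN/bin) separates while the noise floor (~0.01) does not
    distance_threshold: float = 0.02
    min_clone_size: int | None = None
    bulk_depth: int = 500
    n_phased_pairs: int = 200
    clonality_threshold: float = bi.CLONAL_CCF_THRESHOLD
    pigeonhole_tol: float = cv.PIGEONHOLE_TOL

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        errors = validate_config_dict(raw)
        if errors:
            raise ConfigError(errors)
        params = dict(raw.get("params", {}))
        return cls(
            output_dir=base / raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            scenario=raw.get("scenario"),
            cn_matrix_paths={
                tp: base / p for tp, p in raw.get("inputs", {}).get("cn_matrix", {}).items()
            },
            loci_bed=(base / raw["inputs"]["loci_bed"]
                      if raw.get("inputs", {}).get("loci_bed") else None),
            noise_free=bool(params.get("noise_free", False)),
            distance_threshold=float(params.get("distance_threshold", 0.05)),
            min_clone_size=params.get("min_clone_size"),
            bulk_depth=int(params.get("bulk_depth", 500)),
            n_phased_pairs=int(params.get("n_phased_pairs", 200)),
            clonality_threshold=float(params.get("clonality_threshold",
                                                 bi.CLONAL_CCF_THRESHOLD)),
            pigeonhole_tol=float(params.get("pigeonhole_tol", cv.PIGEONHOLE_TOL)),
        )


class ConfigError(ValueError):
    """Raised with the complete list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config_dict(raw: Mapping[str, Any]) -> list[str]:
    """Collect every configuration problem (not just the first)."""
    errors: list[str] = []
    if "output_dir" not in raw:
        errors.append("missing required key 'output_dir'")
    scenario = raw.get("scenario")
    inputs = raw.get("inputs", {})
    if scenario is None and not inputs.get("cn_matrix"):
        errors.append("provide either 'scenario' or inputs.cn_matrix")
    if scenario is not None and scenario not in _SCENARIO_LOCI:
        errors.append(
            f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIO_LOCI)}"
        )
    if inputs.get("cn_matrix") and not inputs.get("loci_bed"):
        errors.append("inputs.cn_matrix requires inputs.loci_bed")
    params = raw.get("params", {})
    if not isinstance(params, Mapping):
        errors.append("'params' must be a mapping")
        params = {}
    for key in ("distance_threshold", "pigeonhole_tol", "clonality_threshold"):
        if key in params:
            try:
                if float(params[key]) <= 0:
                    errors.append(f"params.{key} must be > 0")
            except (TypeError, ValueError):
                errors.append(f"params.{key} must be a number")
    if "bin_width" in params:
        try:
            if int(params["bin_width"]) < 1:
                errors.append("params.bin_width must be >= 1")
        except (TypeError, ValueError):
            errors.append("params.bin_width must be an integer")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("'seed' must be an integer")
    return errors


def validate_config(path: str | Path) -> list[str]:
    """Validate a YAML/JSON config file; returns the (possibly empty) error list."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        return [f"unreadable config: {exc}"]
    if not isinstance(raw, Mapping):
        return ["config must be a mapping"]
    errors = validate_config_dict(raw)
    # input files must exist before any compute
    inputs = raw.get("inputs", {})
    base = Path(path).parent
    for tp, p in inputs.get("cn_matrix", {}).items():
        if not (base / p).exists():
            errors.append(f"inputs.cn_matrix.{tp}: no such file {p}")
    if inputs.get("loci_bed") and not (base / inputs["loci_bed"]).exists():
        errors.append(f"inputs.loci_bed: no such file {inputs['loci_bed']}")
    return errors


@dataclass
class EscapeReport:
    """Combined per-gene evidence; every number equals a stage artifact value."""

    genes: dict[str, dict]
    tree_newick: str
    n_clones: int
    seed: int
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_clones": self.n_clones,
            "tree_newick": self.tree_newick,
            "genes": self.genes,
        }


def run_pipeline(config: PipelineConfig) -> EscapeReport:
    """Run all stages in dependency order; artifacts land in the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    rng = np.random.default_rng(config.seed)

    # -- stage 0: acquire inputs ------------------------------------------
    truth = None
    if config.scenario is not None:
        cohort = sc.preset_scenario(config.scenario)
        if config.noise_free:
            cohort = sc.noise_free(cohort)
        truth = sc.build_truth(cohort)
        matrices = {}
        for tp in TIMEPOINTS:
            m, _labels = sc.simulate_cell_matrix(truth, tp, rng)
            matrices[tp] = m
            path = out / f"cn_matrix_{tp}.tsv"
            gc.write_cn_matrix(m, path)
            manifest[f"cn_matrix_{tp}"] = path.name
        loci = _SCENARIO_LOCI[config.scenario]
    else:
        for tp, p in config.cn_matrix_paths.items():
            if not Path(p).exists():
                raise ConfigError([f"inputs.cn_matrix.{tp}: no such file {p}"])
        if config.loci_bed is None or not Path(config.loci_bed).exists():
            raise ConfigError([f"inputs.loci_bed: no such file {config.loci_bed}"])
        matrices = {tp: gc.read_cn_matrix(p) for tp, p in config.cn_matrix_paths.items()}
        loci = gc.read_bed(config.loci_bed)

    # -- stage 1: locus CN states per timepoint ---------------------------
    log.info("stage cn-state: %d loci x %d timepoints", len(loci), len(matrices))
    summaries: dict[str, dict[str, cs.LocusStateSummary]] = {}
    state_records = []
    for locus in loci:
        summaries[locus.gene] = {}
        for tp, m in matrices.items():
            s = cs.state_fractions(m, locus, tp)
            summaries[locus.gene][tp] = s
            state_records.extend(s.to_records())
    gc.write_report(state_records, out / "locus_states.tsv", "tsv")
    manifest["locus_states"] = "locus_states.tsv"
    deltas = {}
    for gene, by_tp in summaries.items():
        if "pre" in by_tp and "post" in by_tp:
            deltas[gene] = cs.compare_timepoints(by_tp["pre"], by_tp["post"]) \
                .to_dict(orient="records")
    with open(out / "locus_state_deltas.json", "w") as fh:
        json.dump(deltas, fh, indent=2)
    manifest["locus_state_deltas"] = "locus_state_deltas.json"

    # -- stage 2: clone decomposition + tree + fish plot ------------------
    joint = _concat_matrices(list(matrices.values()))
    log.info("stage clones: clustering %d cells", joint.n_cells)
    assignment = cp.cluster_cells(joint, config.min_clone_size,
                                  config.distance_threshold)
    profiles = [cp.consensus_profile(joint, assignment, c)
                for c in assignment.clone_ids]
    tree = cp.infer_tree(profiles)
    per_tp_assign = {}
    for tp, m in matrices.items():
        mapping = {cid: assignment.mapping[cid] for cid in m.cell_ids}
        per_tp_assign[tp] = cp.CloneAssignment(mapping, assignment.clone_ids)
    fish = cp.fishplot_table(tree, per_tp_assign)
    cp.write_assignment(assignment, out / "clone_assignment.tsv")
    cp.write_profiles(profiles, out / "clone_profiles.tsv")
    cp.write_tree(tree, out / "clone_tree.nwk", out / "clone_tree_events.json")
    fish.write(out / "fishplot.tsv", "tsv")
    manifest.update({
        "clone_assignment": "clone_assignment.tsv",
        "clone_profiles": "clone_profiles.tsv",
        "clone_tree": "clone_tree.nwk",
        "fishplot": "fishplot.tsv",
    })

    # -- stage 3: bulk variant CCFs (scenario variants only) --------------
    variant_rows = []
    measured_ccf: dict[str, bi.CCFEstimate] = {}
    if truth is not None and truth.variants:
        purity = truth.config.purity
        for v in truth.variants:
            vaf, alt, depth = sc.simulate_bulk_vaf(
                v, truth, "post", depth=config.bulk_depth, seed=rng)
            cn_t = _bulk_locus_cn(truth, v, "post")
            m_hat = bi.estimate_multiplicity(alt / depth, purity, cn_t)
            est = bi.ccf(None, purity, cn_t, m_hat, alt_count=alt, depth=depth)
            measured_ccf[v.variant_id] = est
            variant_rows.append({
                "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
                "consequence": v.consequence,
                "raw_vaf": alt / depth,
                "corrected_vaf": bi.corrected_vaf(alt / depth, purity, cn_t),
                "ccf": est.ccf, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "clonality": est.clonality,
            })
        gc.write_report(variant_rows, out / "variant_ccf.tsv", "tsv")
        manifest["variant_ccf"] = "variant_ccf.tsv"

    # -- stage 4: per-gene biallelic status + convergence -----------------
    genes: dict[str, dict] = {}
    for locus in loci:
        gene = locus.gene
        post = summaries[gene].get("post")
        dominant_state = max(post.counts, key=lambda s: (post.counts[s], -s))
        muts = [
            bi.GeneMutation(v.consequence, measured_ccf[v.variant_id].clonality)
            for v in (truth.variants if truth is not None else ())
            if _variant_in_locus(v, locus)
        ]
        purity = truth.config.purity if truth is not None else 1.0
        status = bi.biallelic_status(
            gene, bi.PurityContext(purity, dominant_state), muts)

        conv = _convergence_stage(config, truth, locus, summaries[gene],
                                  assignment, profiles, per_tp_assign,
                                  measured_ccf, rng)
        genes[gene] = {
            "states_pre": summaries[gene]["pre"].percentages
            if "pre" in summaries[gene] else {},
            "states_post": post.percentages,
            "biallelic_status": status,
            "variants": [r for r in variant_rows
                         if _row_in_locus(r, locus)],
            "convergence": conv.to_dict() if conv is not None else None,
        }

    cfg_hash = hashlib.sha256(
        json.dumps({
            "scenario": config.scenario, "seed": config.seed,
            "noise_free": config.noise_free,
            "distance_threshold": config.distance_threshold,
        }, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = EscapeReport(genes, tree.to_newick(), len(assignment.clone_ids),
                          config.seed, cfg_hash)
    with open(out / "escape_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=gc._json_default)
        fh.write("\n")
    manifest["escape_report"] = "escape_report.json"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return report


def _concat_matrices(mats: list[gc.CellCNMatrix]) -> gc.CellCNMatrix:
    grid = mats[0].grid
    for m in mats[1:]:
        if m.grid != grid:
            raise ValueError("CN matrices are on different bin grids")
    cells = [c for m in mats for c in m.cell_ids]
    cn = np.vstack([m.cn for m in mats])
    return gc.CellCNMatrix(cells, grid, cn)


def _bulk_locus_cn(truth: sc.CohortTruth, v: sc.VariantSpec, tp: str) -> float:
    """Fraction-weighted tumor CN at the variant position (may be fractional)."""
    fr = truth.fractions[tp]
    return float(sum(fr[c] * truth.locus_cn(c, v.chrom, v.pos)
                     for c in truth.clone_ids))


def _variant_in_locus(v: sc.VariantSpec, locus: gc.LocusDef) -> bool:
    iv = locus.interval
    return gc.norm_chrom(v.chrom) == iv.chrom and iv.start <= v.pos <= iv.end


def _row_in_locus(row: dict, locus: gc.LocusDef) -> bool:
    iv = locus.interval
    return (gc.norm_chrom(row["chrom"]) == iv.chrom
            and iv.start <= row["pos"] <= iv.end)


def _convergence_stage(config, truth, locus, by_tp, assignment, profiles,
                       per_tp_assign, measured_ccf, rng):
    """Assemble inactivating events for one gene and run the convergence call."""
    if truth is None:
        return None
    events: list[cv.InactivatingEvent] = []
    # SNV events with measured CCFs
    snvs = [v for v in truth.variants if _variant_in_locus(v, locus)]
    for v in snvs:
        events.append(cv.InactivatingEvent(
            v.variant_id, locus.gene, v.consequence,
            measured_ccf[v.variant_id].ccf, evidence="bulk reads"))
    # CN-defined events: clone fractions are given inputs (WGS/SV-derived);
    # here they come from generator truth at the post timepoint
    post_fr = truth.fractions["post"]
    for cid in truth.clone_ids:
        if post_fr[cid] <= 0:
            continue
        cn_here = truth.locus_cn(cid, locus.interval.chrom, locus.interval.start)
        if cn_here == 0:
            kind = ("translocation_disruption" if cid == "translocation"
                    else "focal_biallelic_deletion")
            events.append(cv.InactivatingEvent(
                f"cn:{cid}", locus.gene, kind, post_fr[cid],
                evidence="scCNV/WGS fraction"))
    if not events:
        return None
    # phase SNV pairs via simulated read pairs
    calls = {}
    for i in range(len(snvs)):
        for j in range(i + 1, len(snvs)):
            ev = sc.simulate_phased_pairs(
                snvs[i], snvs[j], truth, "post",
                n_pairs=config.n_phased_pairs, seed=rng)
            calls[(snvs[i].variant_id, snvs[j].variant_id)] = cv.phase_call(ev)
    background = sum(
        post_fr[c] for c in truth.clone_ids
        if truth.locus_cn(c, locus.interval.chrom, locus.interval.start) <= 1
        and post_fr[c] > 0
    )
    return cv.detect_convergence(locus.gene, events, calls,
                                 background_ccf=background,
                                 tol=config.pigeonhole_tol)
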