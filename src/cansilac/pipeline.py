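"""Configuration handling and the end-to-end pipeline orchestrator.

A pipeline run either loads a FASTA + PSM table or simulates an
experiment, then executes the analysis stages in order: confidence
filter, incorporation summary, variant pairing, Top3 quantitation,
labeled-set abundance comparison, set enrichment (when an annotation is
supplied), motif discovery, and the resolvability curve.  Outputs are
tab-separated tables plus a JSON manifest recording the seed, a config
hash and input checksums, so two runs with equal manifests have equal
outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import mz_from_mass, peptide_monoisotopic_mass
from .incorporation import (
    filter_quantifiable,
    incorporation_summary,
    labeled_set_abundance_test,
    pair_effect_stats,
    pair_variants,
    set_enrichment,
    site_inventory,
    top3_quant,
)
from .io import read_fasta, read_psm_table, write_fasta, write_psm_table, write_table
from .motifs import extract_windows, motif_discovery
from .resolvability import PeptideIon, fraction_resolved_curve
from .simulate import Condition, SimConfig, simulate_experiment, generate_proteome

__all__ = ["PipelineConfig", "parse_config", "serialize_config", "run_pipeline"]

_DEFAULT_STAGES = (
    "incorporate", "pairs", "quant", "enrich", "motifs", "resolve",
)

_DEFAULT_THRESHOLDS = {
    "pep": 0.01,
    "motif_p": 1.0e-6,
    "motif_min_support": 20,
    "fdr": 0.05,
    "grid_min": 1.0e4,
    "grid_max": 1.0e6,
    "grid_step": 1.0e4,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults applied."""

    seed: int
    output_dir: Path
    fasta: Path | None = None
    psm_table: Path | None = None
    simulation: SimConfig | None = None
    annotation: Path | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _DEFAULT_STAGES}
    )
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_inputs = self.fasta is not None and self.psm_table is not None
        has_sim = self.simulation is not None
        if has_inputs == has_sim:
            raise ValueError(
                "exactly one of {fasta+psm_table, simulation} must be given"
            )
        if self.thresholds["grid_step"] <= 0:
            raise ValueError("grid_step must be positive")
        if not (0.0 <= self.thresholds["pep"] <= 1.0):
            raise ValueError("pep threshold must lie in [0,1]")
        if not (0.0 < self.thresholds["fdr"] <= 1.0):
            raise ValueError("fdr must lie in (0,1]")
        if not (0.0 < self.thresholds["motif_p"] <= 1.0):
            raise ValueError("motif_p must lie in (0,1]")


def _sim_config_from_mapping(block: Mapping[str, Any]) -> SimConfig:
    block = dict(block)
    if "seed" not in block:
        raise ValueError("simulation block is missing mandatory field: seed")
    if "conditions" in block:
        block["conditions"] = tuple(
            Condition(**c) if isinstance(c, Mapping) else c
            for c in block["conditions"]
        )
    known = {f.name for f in dataclass_fields(SimConfig)}
    unknown = sorted(set(block) - known)
    if unknown:
        warnings.warn(f"unknown simulation keys ignored: {unknown}", stacklevel=3)
        for key in unknown:
            block.pop(key)
    return SimConfig(**block)


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration, applying documented defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {
        "seed", "output_dir", "input", "simulation", "annotation",
        "stages", "thresholds", "log_level",
    }
    unknown = sorted(set(raw) - known_top)
    if unknown:
        warnings.warn(f"unknown config keys ignored: {unknown}", stacklevel=2)
    for mandatory in ("seed", "output_dir"):
        if mandatory not in raw:
            raise ValueError(f"config is missing mandatory field: {mandatory}")
    inputs = raw.get("input") or {}
    thresholds = dict(_DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds") or {})
    stages = {s: True for s in _DEFAULT_STAGES}
    stages.update(raw.get("stages") or {})
    sim = raw.get("simulation")
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw["output_dir"]),
        fasta=Path(inputs["fasta"]) if "fasta" in inputs else None,
        psm_table=Path(inputs["psm_table"]) if "psm_table" in inputs else None,
        simulation=_sim_config_from_mapping(sim) if sim is not None else None,
        annotation=Path(raw["annotation"]) if raw.get("annotation") else None,
        stages=stages,
        thresholds=thresholds,
        log_level=str(raw.get("log_level", "INFO")),
    )


def serialize_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through ``parse_config``)."""
    doc: dict[str, Any] = {
        "seed": config.seed,
        "output_dir": str(config.output_dir),
        "stages": config.stages,
        "thresholds": config.thresholds,
        "log_level": config.log_level,
    }
    if config.simulation is not None:
        sim = config.simulation
        doc["simulation"] = {
            "seed": sim.seed,
            "n_proteins": sim.n_proteins,
            "length_mean": sim.length_mean,
            "length_sd": sim.length_sd,
            "length_min": sim.length_min,
            "residue_freqs": dict(sim.residue_freqs),
            "max_missed_cleavages": sim.max_missed_cleavages,
            "min_peptide_length": sim.min_peptide_length,
            "max_peptide_length": sim.max_peptide_length,
            "conditions": [
                {
                    "name": c.name, "n_runs": c.n_runs,
                    "pi_h": c.pi_h, "pi_l": c.pi_l, "pi_cav": c.pi_cav,
                }
                for c in sim.conditions
            ],
            "log_abundance_mean": sim.log_abundance_mean,
            "log_abundance_sd": sim.log_abundance_sd,
            "peptide_log_sd": sim.peptide_log_sd,
            "noise_log_sd": sim.noise_log_sd,
            "missed_cleavage_penalty": sim.missed_cleavage_penalty,
            "response_factor": dict(sim.response_factor),
            "lod": sim.lod,
            "rt_gradient_min": sim.rt_gradient_min,
            "rt_noise_sd_min": sim.rt_noise_sd_min,
            "misassignment_rate": sim.misassignment_rate,
            "freq_floor": sim.freq_floor,
        }
    else:
        doc["input"] = {
            "fasta": str(config.fasta),
            "psm_table": str(config.psm_table),
        }
    if config.annotation is not None:
        doc["annotation"] = str(config.annotation)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    doc = {
        "seed": config.seed,
        "stages": config.stages,
        "thresholds": config.thresholds,
        "simulation": repr(config.simulation),
        "fasta": str(config.fasta),
        "psm_table": str(config.psm_table),
        "annotation": str(config.annotation),
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def _ions_from_records(records: pd.DataFrame) -> list[PeptideIon]:
    ions = []
    for _, row in records.iterrows():
        states = row["site_states"]
        if isinstance(states, str):
            states = tuple(s for s in states.split(",") if s)
        mass = peptide_monoisotopic_mass(row["sequence"], states)
        ions.append(
            PeptideIon(
                mz=mz_from_mass(mass, int(row["charge"])),
                charge=int(row["charge"]),
                sequence=row["sequence"],
            )
        )
    return ions


def _cav_sites(records: pd.DataFrame, state: str) -> list[tuple[str, int]]:
    """(protein, 1-based position) pairs of sites in a given state."""
    sites = []
    for _, row in records.iterrows():
        if not bool(row["proteotypic"]) or pd.isna(row.get("start")):
            continue
        states = row["site_states"]
        if isinstance(states, str):
            states = tuple(s for s in states.split(",") if s)
        arg_positions = [i for i, aa in enumerate(row["sequence"]) if aa == "R"]
        for offset, st in zip(arg_positions, states):
            if state == "any" or st == state:
                sites.append((row["proteins"], int(row["start"]) + offset))
    return sorted(set(sites))


def _read_annotation(path: Path) -> dict[str, set[str]]:
    """Two-column TSV ``term<TAB>protein`` -> term -> protein set."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs columns term, protein")
    term_col, protein_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for term, group in df.groupby(term_col):
        out[str(term)] = set(group[protein_col].astype(str))
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns a report bundle.

    Writes every stage output under ``config.output_dir`` and a
    ``manifest.json`` capturing seed, config hash and input checksums.
    Idempotent for fixed inputs and seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "package": "cansilac",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "inputs": {},
        "stages_run": [],
    }

    def stage_error(stage: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"stage {stage!r} failed: {exc}")

    if config.simulation is not None:
        table, truth = simulate_experiment(config.simulation)
        proteome = generate_proteome(config.simulation)
        write_fasta(proteome, out_dir / "proteome.fasta")
        write_psm_table(table, out_dir / "psms.tsv")
        truth_df = pd.DataFrame(
            {
                "row": np.arange(len(truth.true_states)),
                "true_states": [",".join(s) for s in truth.true_states],
            }
        )
        write_table(truth_df, out_dir / "ground_truth_states.tsv")
        abund_df = pd.DataFrame(
            sorted(truth.protein_abundance.items()),
            columns=["protein", "true_abundance"],
        )
        write_table(abund_df, out_dir / "ground_truth_abundance.tsv")
        manifest["inputs"]["simulation_seed"] = config.simulation.seed
        records = table
    else:
        proteome = read_fasta(config.fasta)
        records = read_psm_table(config.psm_table)
        manifest["inputs"]["fasta_sha256"] = _sha256(Path(config.fasta))
        manifest["inputs"]["psm_table_sha256"] = _sha256(Path(config.psm_table))

    filtered = filter_quantifiable(records, config.thresholds["pep"])
    report["n_records"] = int(len(records))
    report["n_quantifiable"] = int(len(filtered))

    if config.stages.get("incorporate") and len(filtered):
        try:
            summary = incorporation_summary(filtered)
            write_table(summary.table, out_dir / "incorporation_summary.tsv")
            report["incorporation"] = summary
            inventory = site_inventory(filtered)
            report["site_inventory"] = {
                "n_cav_sequences": inventory["n_cav_sequences"],
                "n_cav_sites": inventory["n_cav_sites"],
            }
            manifest["stages_run"].append("incorporate")
        except Exception as exc:
            raise stage_error("incorporate", exc)

    pairs = None
    if config.stages.get("pairs") and len(filtered):
        try:
            pairs = pair_variants(filtered)
            write_table(pairs, out_dir / "variant_pairs.tsv")
            if len(pairs):
                report["pair_stats"] = pair_effect_stats(pairs)
            manifest["stages_run"].append("pairs")
        except Exception as exc:
            raise stage_error("pairs", exc)

    abundances = None
    if config.stages.get("quant") and len(filtered):
        try:
            abundances = top3_quant(filtered)
            write_table(abundances, out_dir / "protein_abundance.tsv")
            if len(abundances) and abundances["cav_labeled"].nunique() == 2:
                report["labeled_set_test"] = labeled_set_abundance_test(abundances)
            manifest["stages_run"].append("quant")
        except Exception as exc:
            raise stage_error("quant", exc)

    if config.stages.get("enrich") and config.annotation is not None and len(filtered):
        try:
            annotation = _read_annotation(Path(config.annotation))
            background = set()
            for value in filtered["proteins"]:
                background.update(str(value).split(";"))
            has_cav = filtered["site_states"].map(
                lambda st: "CAV" in (st if isinstance(st, tuple) else st.split(","))
            )
            foreground = set()
            for value in filtered.loc[has_cav, "proteins"]:
                foreground.update(str(value).split(";"))
            foreground &= background
            enriched = set_enrichment(
                foreground, background, annotation, config.thresholds["fdr"]
            )
            write_table(enriched, out_dir / "enriched_terms.tsv")
            report["n_enriched_terms"] = int(len(enriched))
            manifest["stages_run"].append("enrich")
        except Exception as exc:
            raise stage_error("enrich", exc)

    if config.stages.get("motifs") and len(filtered):
        try:
            fg_sites = _cav_sites(filtered, "CAV")
            bg_sites = _cav_sites(filtered, "any")
            if fg_sites and bg_sites:
                fg = extract_windows(fg_sites, proteome)
                bg = extract_windows(bg_sites, proteome)
                motifs = motif_discovery(
                    fg, bg,
                    p_threshold=config.thresholds["motif_p"],
                    min_support=int(config.thresholds["motif_min_support"]),
                )
                motif_df = pd.DataFrame(
                    [
                        {
                            "pattern": m.pattern_string(),
                            "support": m.support,
                            "fold_enrichment": m.fold_enrichment,
                            "p_values": ";".join(f"{p:.3e}" for p in m.step_p_values),
                        }
                        for m in motifs
                    ],
                    columns=["pattern", "support", "fold_enrichment", "p_values"],
                )
                write_table(motif_df, out_dir / "motifs.tsv")
                report["n_motifs"] = int(len(motif_df))
            manifest["stages_run"].append("motifs")
        except Exception as exc:
            raise stage_error("motifs", exc)

    if config.stages.get("resolve") and len(filtered):
        try:
            grid = np.arange(
                config.thresholds["grid_min"],
                config.thresholds["grid_max"] + config.thresholds["grid_step"] / 2,
                config.thresholds["grid_step"],
            )
            # the resolvability question concerns canavanine-containing
            # ions; fall back to all Arg ions when none carry canavanine
            has_cav = filtered["site_states"].map(
                lambda st: "CAV" in (st if isinstance(st, tuple) else st.split(","))
            )
            subset = filtered.loc[has_cav] if has_cav.any() else filtered
            ions = _ions_from_records(subset)
            curve = fraction_resolved_curve(ions, grid)
            curve_df = pd.DataFrame(
                {"resolution_setting": curve.grid, "fraction_resolved": curve.fraction}
            )
            write_table(curve_df, out_dir / "resolvability_curve.tsv")
            report["resolvability"] = {
                "setting_50": curve.setting_50,
                "setting_95": curve.setting_95,
            }
            manifest["stages_run"].append("resolve")
        except Exception as exc:
            raise stage_error("resolve", exc)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["manifest"] = manifest
    return report
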