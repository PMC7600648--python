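"""Synthetic SILAC / canavanine experiments with known ground truth.

The generator emulates the structure of a heavy-Arg pre-labeled
canavanine incorporation experiment: a random proteome is digested with
LysC (so Arg and canavanine stay internal to peptides), each Arg site of
each peptide draws a label state (heavy Arg / light Arg / canavanine)
from condition-specific occupancy probabilities, and one PSM record is
emitted per observed state-variant with a log-normal MS1 intensity
proportional to the variant's frequency.  A detection limit censors weak
variants, a response factor lets canavanine ionize differently, and a
misassignment rate corrupts reported states to mimic false-positive
identifications.  Every stochastic choice flows from a single seed, so a
fixed configuration reproduces its PSM table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SimConfig",
    "GroundTruth",
    "generate_proteome",
    "digest_lysc",
    "simulate_experiment",
    "DEFAULT_RESIDUE_FREQS",
    "DEFAULT_CONDITIONS",
]

# Approximate human-proteome residue frequencies.
DEFAULT_RESIDUE_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}

# Kyte-Doolittle hydropathy, used as the retention-time proxy.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_STATES = ("H", "L", "CAV")


@dataclass(frozen=True)
class Condition:
    """One treatment arm: replicate runs sharing per-site state odds."""

    name: str
    n_runs: int
    pi_h: float
    pi_l: float
    pi_cav: float

    def __post_init__(self) -> None:
        probs = (self.pi_h, self.pi_l, self.pi_cav)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"state probabilities must lie in [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"state probabilities must sum to 1: {probs}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.pi_h, self.pi_l, self.pi_cav)


# The four study arms: heavy-Arg pre-labeled cells chased for 48 h in
# heavy Arg, light Arg, or canavanine medium (24 h and 48 h), three
# replicate runs each.  Occupancies follow the intensity shares such an
# experiment produces.
DEFAULT_CONDITIONS: tuple[Condition, ...] = (
    Condition("ArgH_48h", 3, 0.9876, 0.0124, 0.0),
    Condition("ArgL_48h", 3, 0.3166, 0.6834, 0.0),
    Condition("CAV_24h", 3, 0.9009, 0.0408, 0.0583),
    Condition("CAV_48h", 3, 0.8349, 0.0388, 0.1263),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic experiment.

    Intensities are arbitrary units on a natural-log scale: a protein's
    base abundance is log-normal(``log_abundance_mean``,
    ``log_abundance_sd``), each peptide multiplies it by a log-normal
    ionization factor, each record by the variant's state-frequency
    product, the state response factor, and multiplicative measurement
    noise.  ``freq_floor`` bounds the enumeration of state variants:
    combinations rarer than it are never emitted.
    """

    seed: int
    n_proteins: int = 100
    length_mean: float = 450.0
    length_sd: float = 150.0
    length_min: int = 60
    residue_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQS)
    )
    max_missed_cleavages: int = 2
    min_peptide_length: int = 7
    max_peptide_length: int = 35
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    log_abundance_mean: float = 15.0
    log_abundance_sd: float = 1.5
    peptide_log_sd: float = 0.8
    noise_log_sd: float = 0.25
    missed_cleavage_penalty: float = 0.2
    response_factor: Mapping[str, float] = field(
        default_factory=lambda: {"H": 1.0, "L": 1.0, "CAV": 0.9}
    )
    lod: float = 1.0e4
    rt_gradient_min: float = 100.0
    rt_noise_sd_min: float = 0.3
    misassignment_rate: float = 0.0
    freq_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.lod < 0:
            raise ValueError("detection limit must be >= 0")
        if not (0.0 <= self.misassignment_rate <= 1.0):
            raise ValueError("misassignment_rate must lie in [0,1]")
        if sum(self.residue_freqs.values()) <= 0:
            raise ValueError("degenerate residue frequency table")


@dataclass
class GroundTruth:
    """True generative quantities behind a simulated PSM table."""

    condition_probs: dict[str, tuple[float, float, float]]
    protein_abundance: dict[str, float]
    true_states: list[tuple[str, ...]]  # pre-misassignment, row-aligned


def generate_proteome(config: SimConfig) -> dict[str, str]:
    """Random protein sequences drawn i.i.d. from the residue table."""
    rng = np.random.default_rng(config.seed)
    residues = sorted(config.residue_freqs)
    probs = np.array([config.residue_freqs[r] for r in residues], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("degenerate residue frequency table")
    probs = probs / probs.sum()
    proteome: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = max(
            config.length_min,
            int(round(rng.normal(config.length_mean, config.length_sd))),
        )
        seq = "".join(rng.choice(list(residues), size=length, p=probs))
        proteome[f"SIM{i:05d}"] = seq
    return proteome


def digest_lysc(sequence: str, max_missed: int = 0) -> list[tuple[str, int]]:
    """LysC digestion products with 1-based start positions.

    Cleaves C-terminal to every Lys, including Lys-Pro bonds (LysC, in
    contrast to trypsin, cleaves before proline).  Products with 0 up to
    ``max_missed`` missed cleavages are enumerated.
    """
    if not sequence:
        raise ValueError("empty sequence")
    boundaries = [0]
    for i, aa in enumerate(sequence):
        if aa == "K":
            boundaries.append(i + 1)
    if boundaries[-1] != len(sequence):
        boundaries.append(len(sequence))
    peptides = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + max_missed, n_frag + 1)):
            start, end = boundaries[i], boundaries[j]
            peptides.append((sequence[start:end], start + 1))
    return peptides


def _enumerate_variants(
    n_sites: int, probs: Sequence[float], floor: float
) -> list[tuple[tuple[str, ...], float]]:
    """All site-state assignments with joint frequency above ``floor``."""
    out: list[tuple[tuple[str, ...], float]] = []

    def rec(prefix: tuple[str, ...], freq: float) -> None:
        if freq < floor:
            return
        if len(prefix) == n_sites:
            out.append((prefix, freq))
            return
        for state, p in zip(_STATES, probs):
            if p > 0.0:
                rec(prefix + (state,), freq * p)

    rec((), 1.0)
    return out


def _charge_probs(length: int) -> np.ndarray:
    if length < 10:
        return np.array([0.20, 0.60, 0.15, 0.05])
    if length <= 20:
        return np.array([0.05, 0.55, 0.30, 0.10])
    return np.array([0.02, 0.35, 0.45, 0.18])


def simulate_experiment(
    config: SimConfig, proteome: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a PSM table and its ground truth.

    Returns ``(table, truth)`` where ``table`` has the standard PSM
    columns plus ``start`` (1-based peptide start for proteotypic
    peptides) and ``truth`` records the generative parameters and the
    pre-misassignment states of every row.
    """
    if proteome is None:
        proteome = generate_proteome(config)
    rng = np.random.default_rng(config.seed + 1)

    # digest once; map sequence -> owning proteins
    # only peptides inside the identifiable length window are observed,
    # mimicking the search space of an identification engine
    peptide_owners: dict[str, set[str]] = {}
    peptide_start: dict[str, tuple[str, int]] = {}
    for pid in sorted(proteome):
        for pep, start in digest_lysc(proteome[pid], config.max_missed_cleavages):
            if not (config.min_peptide_length <= len(pep) <= config.max_peptide_length):
                continue
            peptide_owners.setdefault(pep, set()).add(pid)
            peptide_start.setdefault(pep, (pid, start))
    peptides = sorted(peptide_owners)
    if not any("R" in p for p in peptides):
        raise ValueError("no Arg-containing peptide in the digested proteome")

    protein_abundance = {
        pid: float(
            np.exp(rng.normal(config.log_abundance_mean, config.log_abundance_sd))
        )
        for pid in sorted(proteome)
    }
    peptide_factor = {
        pep: float(np.exp(rng.normal(0.0, config.peptide_log_sd)))
        for pep in peptides
    }
    # peptide base abundance: mean owner abundance times ionization
    # factor, down-weighted per missed cleavage (digestion is efficient,
    # so longer missed-cleavage products are rare)
    peptide_base = {
        pep: (
            sum(protein_abundance[pid] for pid in peptide_owners[pep])
            / len(peptide_owners[pep])
        )
        * peptide_factor[pep]
        * config.missed_cleavage_penalty ** pep[:-1].count("K")
        for pep in peptides
    }

    # peptide-level chromatographic/charge behavior, shared by all
    # variants (canavanine shows no charge or RT effect)
    kd_center = {}
    charge_of = {}
    for pep in peptides:
        kd = sum(_KYTE_DOOLITTLE.get(aa, 0.0) for aa in pep) / len(pep)
        frac = min(max((kd + 4.5) / 9.0, 0.02), 0.98)
        kd_center[pep] = frac * config.rt_gradient_min
        charge_of[pep] = int(
            rng.choice([1, 2, 3, 4], p=_charge_probs(len(pep)))
        )

    resp = dict(config.response_factor)
    rows: list[dict] = []
    true_states: list[tuple[str, ...]] = []
    for condition in config.conditions:
        for run_idx in range(condition.n_runs):
            run_id = f"{condition.name}_r{run_idx + 1}"
            for pep in peptides:
                n_sites = pep.count("R")
                if n_sites == 0:
                    variants = [((), 1.0)]
                else:
                    variants = _enumerate_variants(
                        n_sites, condition.probs, config.freq_floor
                    )
                for states, freq in variants:
                    response = math.prod(resp[s] for s in states) if states else 1.0
                    intensity = (
                        peptide_base[pep]
                        * freq
                        * response
                        * float(np.exp(rng.normal(0.0, config.noise_log_sd)))
                    )
                    if intensity < config.lod:
                        continue
                    reported = list(states)
                    if config.misassignment_rate > 0:
                        for i, s in enumerate(reported):
                            if rng.random() < config.misassignment_rate:
                                others = [o for o in _STATES if o != s]
                                reported[i] = others[int(rng.integers(2))]
                    owners = sorted(peptide_owners[pep])
                    proteotypic = len(owners) == 1
                    rt = kd_center[pep] + float(
                        rng.normal(0.0, config.rt_noise_sd_min)
                    )
                    rt = min(max(rt, 0.0), config.rt_gradient_min)
                    pep_score = min(float(rng.exponential(0.004)), 1.0)
                    rows.append(
                        {
                            "run": run_id,
                            "condition": condition.name,
                            "sequence": pep,
                            "site_states": ",".join(reported),
                            "proteins": ";".join(owners),
                            "proteotypic": proteotypic,
                            "charge": charge_of[pep],
                            "rt_min": round(rt, 4),
                            "intensity": round(intensity, 4),
                            "pep": round(pep_score, 6),
                            "start": peptide_start[pep][1] if proteotypic else np.nan,
                        }
                    )
                    true_states.append(states)

    table = pd.DataFrame(
        rows,
        columns=[
            "run", "condition", "sequence", "site_states", "proteins",
            "proteotypic", "charge", "rt_min", "intensity", "pep", "start",
        ],
    )
    truth = GroundTruth(
        condition_probs={c.name: c.probs for c in config.conditions},
        protein_abundance=protein_abundance,
        true_states=true_states,
    )
    return table, truth


def single_condition_config(
    seed: int,
    pi_cav: float,
    pi_l: float = 0.0,
    n_runs: int = 3,
    **overrides,
) -> SimConfig:
    """Convenience: one condition with given occupancies (rest heavy)."""
    pi_h = 1.0 - pi_l - pi_cav
    cond = Condition("sim", n_runs, pi_h, pi_l, pi_cav)
    return replace(SimConfig(seed=seed), conditions=(cond,), **overrides)
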