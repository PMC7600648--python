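"""Quantification of label-state incorporation from PSM tables.

Each record is one identified peptide variant with per-Arg-site label
states (heavy Arg ``H``, light Arg ``L``, canavanine ``CAV``), MS1
intensity and metadata.  The operations here reproduce the downstream
analysis of a SILAC heavy-Arg / canavanine experiment:

* filtering to confidently identified Arg-containing peptides,
* per-condition incorporation shares by identifications and by intensity
  (with across-replicate SD),
* inventory of canavanine peptide sequences and protein sites,
* pairing of single-canavanine variants with their all-heavy
  counterparts within a run, and summaries of charge / retention time /
  intensity effects,
* Top3 protein quantitation over proteotypic peptides,
* a rank-sum comparison of canavanine-labeled versus unlabeled protein
  abundances, and a generic hypergeometric set-enrichment stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LABEL_STATES",
    "PSM_COLUMNS",
    "IncorporationSummary",
    "filter_quantifiable",
    "incorporation_summary",
    "site_inventory",
    "pair_variants",
    "pair_effect_stats",
    "top3_quant",
    "labeled_set_abundance_test",
    "set_enrichment",
    "parse_site_states",
]

LABEL_STATES = ("H", "L", "CAV")

#: Required columns of a PSM table.
PSM_COLUMNS = (
    "run",
    "condition",
    "sequence",
    "site_states",
    "proteins",
    "proteotypic",
    "charge",
    "rt_min",
    "intensity",
    "pep",
)


def parse_site_states(value: str) -> tuple[str, ...]:
    """Split a comma-joined site-state field into a tuple of states."""
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return ()
    states = tuple(s.strip() for s in str(value).split(","))
    for s in states:
        if s not in LABEL_STATES:
            raise ValueError(f"unknown label state {s!r} in {value!r}")
    return states


def _states_column(records: pd.DataFrame) -> pd.Series:
    return records["site_states"].map(
        lambda v: v if isinstance(v, tuple) else parse_site_states(v)
    )


def filter_quantifiable(
    records: pd.DataFrame, pep_threshold: float = 0.01
) -> pd.DataFrame:
    """Keep confident identifications of Arg/canavanine-bearing peptides.

    A record survives when its posterior error probability is at or
    below ``pep_threshold`` and its sequence carries at least one
    Arg/canavanine site.
    """
    states = _states_column(records)
    keep = (records["pep"] <= pep_threshold) & (states.map(len) > 0)
    out = records.loc[keep].copy()
    out["site_states"] = states.loc[keep]
    return out


@dataclass(frozen=True)
class IncorporationSummary:
    """Per-condition label-state shares, averaged across replicate runs.

    ``table`` has one row per (condition, state) with columns
    ``id_share``, ``id_sd``, ``intensity_share``, ``intensity_sd``
    (shares in percent; SD absent — NaN — for single-run conditions).
    """

    table: pd.DataFrame
    convention: str


def _run_shares(states: Iterable[tuple[str, ...]], intensities: Iterable[float],
                convention: str) -> tuple[dict[str, float], dict[str, float]]:
    """Identification and intensity shares (%) within one run."""
    counts = dict.fromkeys(LABEL_STATES, 0.0)
    weights = dict.fromkeys(LABEL_STATES, 0.0)
    for site_states, intensity in zip(states, intensities):
        if convention == "site":
            for s in site_states:
                counts[s] += 1.0
                weights[s] += float(intensity)
        else:  # peptide-level: a record must be in a single pure state
            unique = set(site_states)
            if len(unique) != 1:
                raise ValueError(
                    "peptide-level convention cannot classify a mixed-state "
                    f"record with states {site_states}"
                )
            (s,) = unique
            counts[s] += 1.0
            weights[s] += float(intensity)
    n, w = sum(counts.values()), sum(weights.values())
    if n == 0:
        raise ValueError("run contains no Arg/canavanine observations")
    id_share = {s: 100.0 * counts[s] / n for s in LABEL_STATES}
    int_share = {s: (100.0 * weights[s] / w if w > 0 else float("nan"))
                 for s in LABEL_STATES}
    return id_share, int_share


def incorporation_summary(
    records: pd.DataFrame, convention: str = "site"
) -> IncorporationSummary:
    """Label-state incorporation shares per condition.

    Under the default site convention every Arg/canavanine site of every
    record is one observation carrying the record's full intensity as
    weight, so the intensity share of CAV estimates the proportion of
    canavanine at all residues normally occupied by arginine.  Shares
    are computed within each run, then averaged (mean +- SD) across the
    replicate runs of a condition.
    """
    if convention not in ("site", "peptide"):
        raise ValueError(f"unknown counting convention: {convention!r}")
    if len(records) == 0:
        raise ValueError("no records to summarize")
    states = _states_column(records)
    rows = []
    for condition, cond_df in records.groupby("condition", sort=True):
        per_run_id: dict[str, list[float]] = {s: [] for s in LABEL_STATES}
        per_run_int: dict[str, list[float]] = {s: [] for s in LABEL_STATES}
        runs = cond_df.groupby("run", sort=True)
        for _, run_df in runs:
            id_share, int_share = _run_shares(
                states.loc[run_df.index], run_df["intensity"], convention
            )
            for s in LABEL_STATES:
                per_run_id[s].append(id_share[s])
                per_run_int[s].append(int_share[s])
        n_runs = len(per_run_id["H"])
        for s in LABEL_STATES:
            ids = np.array(per_run_id[s])
            ints = np.array(per_run_int[s])
            rows.append(
                {
                    "condition": condition,
                    "state": s,
                    "id_share": ids.mean(),
                    "id_sd": ids.std(ddof=1) if n_runs > 1 else float("nan"),
                    "intensity_share": ints.mean(),
                    "intensity_sd": ints.std(ddof=1) if n_runs > 1 else float("nan"),
                    "n_runs": n_runs,
                }
            )
    table = pd.DataFrame(rows)
    return IncorporationSummary(table=table, convention=convention)


def site_inventory(records: pd.DataFrame) -> dict[str, object]:
    """Count unique canavanine peptide sequences and protein sites.

    Sites are (protein accession, 1-based protein position) pairs and
    require a ``start`` column (peptide start within the protein).
    Records without a usable locator are counted by sequence only and
    reported under ``unmapped_sequences``.
    """
    states = _states_column(records)
    has_cav = states.map(lambda st: "CAV" in st)
    cav_df = records.loc[has_cav]
    sequences = set(cav_df["sequence"])
    sites: set[tuple[str, int]] = set()
    unmapped: set[str] = set()
    mappable = "start" in cav_df.columns
    for idx, row in cav_df.iterrows():
        start = row.get("start") if mappable else None
        proteins = str(row["proteins"]).split(";")
        if (
            start is None
            or (isinstance(start, float) and math.isnan(start))
            or len(proteins) != 1
        ):
            unmapped.add(row["sequence"])
            continue
        arg_positions = [i for i, aa in enumerate(row["sequence"]) if aa == "R"]
        for pos, state in zip(arg_positions, states.loc[idx]):
            if state == "CAV":
                sites.add((proteins[0], int(start) + pos))
    return {
        "n_cav_sequences": len(sequences),
        "n_cav_sites": len(sites),
        "unmapped_sequences": sorted(unmapped),
    }


def pair_variants(records: pd.DataFrame) -> pd.DataFrame:
    """Pair single-canavanine variants with the all-heavy variant.

    For each (sequence, run): the variant with exactly one CAV site and
    all remaining sites heavy is paired with the all-heavy variant of
    the same sequence in the same run.  Records containing light Arg or
    more than one CAV do not participate.  When a variant was observed
    as several features (e.g. charge states) the most intense one
    represents it.

    Returns a DataFrame with one row per pair: sequence, run, heavy and
    CAV intensities, intensity ratio (heavy/CAV), RT delta (CAV - heavy,
    minutes), and the two charges.
    """
    states = _states_column(records)

    def classify(st: tuple[str, ...]) -> str:
        if all(s == "H" for s in st):
            return "all_H"
        if st.count("CAV") == 1 and all(s in ("H", "CAV") for s in st):
            return "single_CAV"
        return "other"

    df = records.copy()
    df["_class"] = states.map(classify)
    rows = []
    for (seq, run), group in df.groupby(["sequence", "run"], sort=True):
        heavies = group[group["_class"] == "all_H"]
        cavs = group[group["_class"] == "single_CAV"]
        if heavies.empty or cavs.empty:
            continue
        heavy = heavies.loc[heavies["intensity"].idxmax()]
        for _, cav in cavs.sort_index().iterrows():
            rows.append(
                {
                    "sequence": seq,
                    "run": run,
                    "heavy_intensity": heavy["intensity"],
                    "cav_intensity": cav["intensity"],
                    "intensity_ratio": (
                        heavy["intensity"] / cav["intensity"]
                        if cav["intensity"] > 0
                        else float("nan")
                    ),
                    "rt_delta_min": cav["rt_min"] - heavy["rt_min"],
                    "heavy_charge": int(heavy["charge"]),
                    "cav_charge": int(cav["charge"]),
                }
            )
    columns = [
        "sequence", "run", "heavy_intensity", "cav_intensity",
        "intensity_ratio", "rt_delta_min", "heavy_charge", "cav_charge",
    ]
    return pd.DataFrame(rows, columns=columns)


def pair_effect_stats(pairs: pd.DataFrame, alpha: float = 0.05) -> dict[str, object]:
    """Summaries of canavanine effects on intensity, RT and charge.

    Reports the median heavy/CAV intensity ratio (over all pairs and
    deduplicated by sequence), a Wilcoxon signed-rank test of the RT
    deltas, and an exact sign test of charge changes.  Tests require at
    least 6 pairs; with fewer they are skipped with a notice.
    """
    if len(pairs) == 0:
        raise ValueError("no variant pairs to summarize")
    valid_ratio = pairs["intensity_ratio"].dropna()
    n_excluded = len(pairs) - len(valid_ratio)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} pair(s) with zero canavanine intensity excluded "
            "from the ratio summary",
            stacklevel=2,
        )
    dedup = (
        pairs.dropna(subset=["intensity_ratio"])
        .groupby("sequence")["intensity_ratio"]
        .median()
    )
    out: dict[str, object] = {
        "n_pairs": int(len(pairs)),
        "median_intensity_ratio": float(valid_ratio.median()),
        "median_intensity_ratio_by_sequence": float(dedup.median()),
        "median_rt_delta_min": float(pairs["rt_delta_min"].median()),
        "alpha": alpha,
    }
    charge_change = (pairs["cav_charge"] - pairs["heavy_charge"]).astype(int)
    out["charge_change_table"] = charge_change.value_counts().sort_index().to_dict()
    if len(pairs) < 6:
        out["tests"] = "skipped: fewer than 6 pairs"
        return out
    deltas = pairs["rt_delta_min"].to_numpy(float)
    if np.allclose(deltas, 0):
        out["rt_wilcoxon_p"] = 1.0
    else:
        out["rt_wilcoxon_p"] = float(stats.wilcoxon(deltas).pvalue)
    out["rt_significant"] = bool(out["rt_wilcoxon_p"] < alpha)
    n_up = int((charge_change > 0).sum())
    n_down = int((charge_change < 0).sum())
    if n_up + n_down == 0:
        out["charge_sign_p"] = 1.0
    else:
        out["charge_sign_p"] = float(
            stats.binomtest(n_up, n_up + n_down, 0.5).pvalue
        )
    out["charge_significant"] = bool(out["charge_sign_p"] < alpha)
    return out


def top3_quant(
    records: pd.DataFrame, feature_aggregate: str = "max"
) -> pd.DataFrame:
    """Top3 protein abundances from proteotypic peptides.

    A peptide's intensity is the maximum (default) or sum over its
    records; a protein's abundance is the mean of its three most intense
    proteotypic peptides (mean of two when only two exist).  Proteins
    with fewer than two proteotypic peptides are excluded.  The returned
    table flags proteins with at least one canavanine-bearing record.
    """
    if feature_aggregate not in ("max", "sum"):
        raise ValueError(f"unknown feature aggregate: {feature_aggregate!r}")
    states = _states_column(records)
    df = records.copy()
    df["_has_cav"] = states.map(lambda st: "CAV" in st)
    proteo = df[df["proteotypic"].astype(bool)]
    cav_proteins: set[str] = set()
    for _, row in df[df["_has_cav"]].iterrows():
        cav_proteins.update(str(row["proteins"]).split(";"))
    rows = []
    agg = "max" if feature_aggregate == "max" else "sum"
    for protein, group in proteo.groupby("proteins", sort=True):
        pep_int = group.groupby("sequence")["intensity"].agg(agg)
        if len(pep_int) < 2:
            continue
        top = pep_int.sort_values(ascending=False).head(3)
        rows.append(
            {
                "protein": protein,
                "top3_abundance": float(top.mean()),
                "n_proteotypic_peptides": int(len(pep_int)),
                "cav_labeled": protein in cav_proteins,
            }
        )
    columns = ["protein", "top3_abundance", "n_proteotypic_peptides", "cav_labeled"]
    return pd.DataFrame(rows, columns=columns)


def labeled_set_abundance_test(abundances: pd.DataFrame) -> dict[str, object]:
    """Mann-Whitney U comparison of labeled vs unlabeled protein abundance.

    Two-sided test between the Top3 abundances of canavanine-labeled and
    unlabeled proteins, with the direction of the median difference.
    Skipped (with a notice) when either group has fewer than 3 members.
    """
    labeled = abundances.loc[abundances["cav_labeled"], "top3_abundance"]
    unlabeled = abundances.loc[~abundances["cav_labeled"], "top3_abundance"]
    if len(labeled) == 0 or len(unlabeled) == 0:
        raise ValueError("both labeled and unlabeled groups must be non-empty")
    out: dict[str, object] = {
        "n_labeled": int(len(labeled)),
        "n_unlabeled": int(len(unlabeled)),
        "median_labeled": float(labeled.median()),
        "median_unlabeled": float(unlabeled.median()),
    }
    diff = out["median_labeled"] - out["median_unlabeled"]
    out["direction"] = "positive" if diff > 0 else ("negative" if diff < 0 else "none")
    if len(labeled) < 3 or len(unlabeled) < 3:
        out["test"] = "skipped: a group has fewer than 3 proteins"
        return out
    u = stats.mannwhitneyu(labeled, unlabeled, alternative="two-sided")
    out["U"] = float(u.statistic)
    out["p_value"] = float(u.pvalue)
    return out


def set_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    For each term: the upper tail probability of drawing at least the
    observed number of term members when sampling ``|foreground|``
    proteins from the background without replacement.  P-values are
    Benjamini-Hochberg adjusted across terms; rows passing ``fdr`` are
    returned with fold enrichment.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise ValueError(f"foreground is not a subset of background (e.g. {extra})")
    if not annotation:
        raise ValueError("empty annotation")
    N, n = len(bg), len(fg)
    rows = []
    for term, members in sorted(annotation.items()):
        term_bg = set(members) & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append({"term": term, "k": k, "K": K, "p": p, "fold_enrichment": fold})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "K", "p", "p_adj", "fold_enrichment"])
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    enriched = table[table["p_adj"] <= fdr].sort_values("p").reset_index(drop=True)
    return enriched[["term", "k", "K", "p", "p_adj", "fold_enrichment"]]
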