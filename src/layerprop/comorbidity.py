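"""Disease co-occurrence scoring experiment and shared-symptom enrichment.

The evaluation follows the disease-scoring protocol on a two-layer
symptom-disease network: a target disease gets label 1, a random 20% of its
known co-occurring diseases are revealed as prior labels, a chosen fraction
of the target's related symptoms (those sharing an inter-layer edge with it)
are labeled 1, all other nodes stay 0. Scores from the multi-layer solver
rank the remaining diseases; ranking quality against the co-occurrence truth
is measured by AUC. The target iterates over every disease with at least one
co-occurring partner (leave-one-target-out), label draws are repeated, and
the symptom label fraction sweeps 0-100% in 20% steps; 0% is the reference
condition in which the inter-layer links are dropped and the disease layer
is solved alone.

Revealed prior diseases are excluded from the AUC truth set — they were
handed to the solver as labels, so counting them as test positives would
leak. The enrichment analysis asks whether co-occurring disease pairs share
more symptoms than non-co-occurring ones: per target disease, the difference
between the mean shared-symptom count with co-occurring vs non-co-occurring
partners, tested with a paired one-sided t (alternative: co-occurring mean
is higher, df = retained diseases - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata, t as t_dist

from .network import MultiLayerNetwork, separate
from .propagation import (
    LabelVector,
    ScoreVector,
    SSLParameters,
    laplacian,
    system_matrix,
)
from .nystrom import BlockDiagonalSPD, nystrom, woodbury_solve

DEFAULT_MU_GRID: tuple[tuple[float, float], ...] = tuple(
    (a, b) for a in (0.01, 0.1, 1.0, 10.0, 100.0) for b in (0.01, 0.1, 1.0, 10.0, 100.0)
)


class CooccurrenceTable:
    """Set of unordered disease-id pairs known to co-occur."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        normalized = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} not allowed")
            normalized.add((a, b) if a <= b else (b, a))
        self.pairs: frozenset[tuple[str, str]] = frozenset(normalized)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.pairs

    def neighbors(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out

    def validate_against(self, network: MultiLayerNetwork, disease_layer: str) -> None:
        ids = set(network.layers[network.layer_index(disease_layer)].node_ids)
        for a, b in self.pairs:
            for x in (a, b):
                if x not in ids:
                    raise ValueError(f"co-occurrence id {x!r} not in layer {disease_layer!r}")


@dataclass
class ExperimentConfig:
    """Protocol parameters for the co-occurrence scoring experiment.

    ``target_disease``/``symptom_label_fraction`` address a single labeling
    (:func:`build_labels`); the sweep fields drive :func:`run_experiment`.
    """

    target_disease: str | None = None
    symptom_label_fraction: float = 1.0
    prior_cooccurrence_fraction: float = 0.2
    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    mu_grid: tuple[tuple[float, float], ...] = DEFAULT_MU_GRID
    repeats: int = 10
    seed: int = 0
    disease_layer: str = "disease"
    symptom_layer: str = "symptom"
    targets: tuple[str, ...] | None = None
    solver: str = "direct"  # "direct" or "fast"
    rank: int | None = None  # Nystrom sample size for the fast solver

    def __post_init__(self) -> None:
        for frac in (self.symptom_label_fraction, self.prior_cooccurrence_fraction, *self.fractions):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.solver not in ("direct", "fast"):
            raise ValueError("solver must be 'direct' or 'fast'")


@dataclass
class LabelAssignment:
    """A concrete labeling draw: the label vector plus what was revealed."""

    labels: LabelVector
    target: str
    prior_diseases: tuple[str, ...]
    labeled_symptoms: tuple[str, ...]


@dataclass
class ExperimentResult:
    """Sweep output: tidy per-(grid point, fraction, repeat, target) records."""

    records: pd.DataFrame
    chosen_params: tuple[float, float]
    mean_auc_by_fraction: dict[float, float]
    n_skipped_targets: int = 0

    def per_target_auc(self, fraction: float) -> dict[str, np.ndarray]:
        """Target -> per-repeat AUC array at the chosen parameters."""
        mu_a, mu_b = self.chosen_params
        sub = self.records[
            (self.records["mu_a"] == mu_a)
            & (self.records["mu_b"] == mu_b)
            & (self.records["fraction"] == fraction)
        ]
        return {
            target: grp.sort_values("repeat")["auc"].to_numpy()
            for target, grp in sub.groupby("target")
        }

    def summary(self) -> pd.DataFrame:
        """(fraction, mean_auc, sd) at the chosen parameters."""
        mu_a, mu_b = self.chosen_params
        sub = self.records[
            (self.records["mu_a"] == mu_a) & (self.records["mu_b"] == mu_b)
        ]
        grp = sub.groupby("fraction")["auc"]
        return pd.DataFrame(
            {"fraction": grp.mean().index, "mean_auc": grp.mean().values, "sd": grp.std().values}
        ).reset_index(drop=True)


def auc(scores: Sequence[float], binary_truth: Sequence[int]) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counted one half. Equals the Mann-Whitney U statistic
    normalized by n_pos * n_neg."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_truth).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length vectors")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain at least one positive and one negative")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _disease_symptom_view(
    network: MultiLayerNetwork, disease_layer: str, symptom_layer: str
) -> tuple[int, int, np.ndarray]:
    """(disease layer index, symptom layer index, disease x symptom inter block)."""
    d_idx = network.layer_index(disease_layer)
    s_idx = network.layer_index(symptom_layer)
    if abs(d_idx - s_idx) != 1:
        raise ValueError("disease and symptom layers must be adjacent")
    if d_idx < s_idx:
        blk = network.inter_blocks[d_idx]
    else:
        blk = network.inter_blocks[s_idx].T
    return d_idx, s_idx, np.asarray(blk, dtype=float)


def _prior_count(n_cooc: int, fraction: float) -> int:
    # nearest-integer share, but always leave >= 1 partner for evaluation
    return min(int(round(fraction * n_cooc)), n_cooc - 1)


def build_labels(
    network: MultiLayerNetwork,
    config: ExperimentConfig,
    cooccurrence: CooccurrenceTable,
    rng: np.random.Generator | None = None,
) -> LabelAssignment:
    """Draw one labeling for ``config.target_disease``.

    The target is labeled 1; a seeded random ``prior_cooccurrence_fraction``
    of its co-occurring diseases and a random ``symptom_label_fraction`` of
    its related symptoms (non-zero inter-layer edge) are labeled 1; every
    other node is 0.
    """
    if config.target_disease is None:
        raise ValueError("config.target_disease must be set")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d_idx, _, inter = _disease_symptom_view(network, config.disease_layer, config.symptom_layer)
    d_layer = network.layers[d_idx]
    target = config.target_disease
    t_local = d_layer.node_ids.index(target) if target in d_layer.node_ids else -1
    if t_local < 0:
        raise KeyError(f"target disease {target!r} not in layer {config.disease_layer!r}")

    partners = sorted(cooccurrence.neighbors().get(target, set()))
    if not partners:
        raise ValueError(f"target {target!r} has no co-occurring diseases")
    k_prior = _prior_count(len(partners), config.prior_cooccurrence_fraction)
    prior = tuple(sorted(rng.choice(partners, size=k_prior, replace=False))) if k_prior else ()

    s_layer = network.layers[network.layer_index(config.symptom_layer)]
    related = [s_layer.node_ids[j] for j in np.flatnonzero(inter[t_local] > 0)]
    k_sym = int(round(config.symptom_label_fraction * len(related)))
    labeled_symptoms = (
        tuple(sorted(rng.choice(related, size=k_sym, replace=False))) if k_sym else ()
    )

    values = np.zeros(network.total_size)
    values[network.node_index(config.disease_layer, target)] = 1.0
    for d in prior:
        values[network.node_index(config.disease_layer, d)] = 1.0
    for s in labeled_symptoms:
        values[network.node_index(config.symptom_layer, s)] = 1.0
    return LabelAssignment(
        labels=LabelVector(values),
        target=target,
        prior_diseases=prior,
        labeled_symptoms=labeled_symptoms,
    )


def run_experiment(
    network: MultiLayerNetwork,
    cooccurrence: CooccurrenceTable,
    config: ExperimentConfig,
) -> ExperimentResult:
    """Leave-one-target-out co-occurrence scoring sweep.

    For every grid point, symptom-label fraction, repeat and target disease:
    draw labels, solve the SSL system (multi-layer for fraction > 0; disease
    layer alone at fraction 0), and score the AUC of the remaining diseases
    against the target's co-occurrence partners, excluding the target and the
    revealed priors from the truth set. Parameters are chosen from the grid by
    best overall mean AUC. Label draws are deterministic in ``config.seed``
    and shared across grid points.
    """
    cooccurrence.validate_against(network, config.disease_layer)
    d_idx, _, inter = _disease_symptom_view(network, config.disease_layer, config.symptom_layer)
    d_layer = network.layers[d_idx]
    disease_ids = d_layer.node_ids
    n_d = d_layer.size
    d_slice = network.layer_slice(d_idx)
    local = {nid: i for i, nid in enumerate(disease_ids)}
    nbrs = cooccurrence.neighbors()

    targets = list(config.targets) if config.targets else [
        d for d in disease_ids if nbrs.get(d)
    ]
    if not targets:
        raise ValueError("no target disease has co-occurring partners")

    sep = separate(network)
    w_disease = network.intra_blocks[d_idx]
    n_skipped = 0

    # one label draw per (fraction, repeat, target), reused across the grid
    draws: dict[int, list[tuple[str, int, np.ndarray, np.ndarray, np.ndarray]]] = {}
    for fi, frac in enumerate(config.fractions):
        cols = []
        for rep in range(config.repeats):
            for ti, target in enumerate(targets):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=config.seed, spawn_key=(fi, rep, ti))
                )
                cfg = ExperimentConfig(
                    target_disease=target,
                    symptom_label_fraction=frac,
                    prior_cooccurrence_fraction=config.prior_cooccurrence_fraction,
                    disease_layer=config.disease_layer,
                    symptom_layer=config.symptom_layer,
                )
                assign = build_labels(network, cfg, cooccurrence, rng)
                hidden = set(assign.prior_diseases) | {target}
                eval_idx = np.array(
                    [local[d] for d in disease_ids if d not in hidden], dtype=int
                )
                truth = np.array(
                    [d in nbrs.get(target, set()) for d in disease_ids if d not in hidden],
                    dtype=bool,
                )
                if truth.sum() == 0 or truth.sum() == truth.size:
                    n_skipped += 1
                    continue
                y_full = assign.labels.values
                y = y_full[d_slice] if frac == 0.0 else y_full
                cols.append((target, rep, y, eval_idx, truth))
        draws[fi] = cols

    rows = []
    single_factors: dict[float, tuple] = {}
    for mu_a, mu_b in config.mu_grid:
        params = SSLParameters(mu_a=mu_a, mu_b=mu_b)
        solve_full = _make_batch_solver(sep, params, config)
        if mu_a not in single_factors:
            m0 = np.eye(n_d) + mu_a * laplacian(w_disease, check=False)
            single_factors[mu_a] = cho_factor(m0)
        fac0 = single_factors[mu_a]
        for fi, frac in enumerate(config.fractions):
            cols = draws[fi]
            if not cols:
                continue
            ymat = np.column_stack([c[2] for c in cols])
            if frac == 0.0:
                fmat = cho_solve(fac0, ymat)
                disease_scores = fmat
            else:
                fmat = solve_full(ymat)
                disease_scores = fmat[d_slice]
            for j, (target, rep, _y, eval_idx, truth) in enumerate(cols):
                rows.append(
                    {
                        "mu_a": mu_a,
                        "mu_b": mu_b,
                        "fraction": frac,
                        "repeat": rep,
                        "target": target,
                        "auc": auc(disease_scores[eval_idx, j], truth),
                    }
                )

    records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("no evaluable (target, repeat) combinations")
    by_grid = records.groupby(["mu_a", "mu_b"])["auc"].mean()
    chosen = by_grid.idxmax()
    sub = records[(records["mu_a"] == chosen[0]) & (records["mu_b"] == chosen[1])]
    mean_by_frac = sub.groupby("fraction")["auc"].mean().to_dict()
    return ExperimentResult(
        records=records,
        chosen_params=(float(chosen[0]), float(chosen[1])),
        mean_auc_by_fraction={float(k): float(v) for k, v in mean_by_frac.items()},
        n_skipped_targets=n_skipped,
    )


def _make_batch_solver(sep, params: SSLParameters, config: ExperimentConfig):
    """Batched multi-column solver for the full two-layer system."""
    if config.solver == "direct" or params.mu_b == 0:
        fac = cho_factor(system_matrix(sep, params))
        return lambda ymat: cho_solve(fac, ymat)
    r = config.rank if config.rank is not None else sep.total_size
    a_op = BlockDiagonalSPD(
        [
            np.eye(blk.shape[0]) + params.mu_a * laplacian(blk, check=False)
            for blk in sep.intra_blocks
        ]
    )
    factor = nystrom(laplacian(sep.W_inter, check=False), r, config.seed, check=False)
    if factor.effective_rank == 0:
        return a_op.solve
    core = params.mu_b * np.diag(1.0 / factor.core_eigvals)
    return lambda ymat: woodbury_solve(a_op, factor.U, core, ymat)


@dataclass
class EnrichmentResult:
    """Paired one-sided t-test of shared-symptom enrichment in co-occurring pairs."""

    t_statistic: float
    p_value: float
    df: int
    sd: float
    per_disease_differences: np.ndarray
    diseases: tuple[str, ...]
    n_dropped: int
    degenerate: bool = False  # zero-variance differences


def shared_symptom_counts(
    network: MultiLayerNetwork,
    disease_layer: str = "disease",
    symptom_layer: str = "symptom",
) -> np.ndarray:
    """Disease x disease matrix of common inter-layer (symptom) neighbors."""
    _, _, inter = _disease_symptom_view(network, disease_layer, symptom_layer)
    b = (inter > 0).astype(float)
    return b @ b.T


def _enrichment_differences(
    network: MultiLayerNetwork,
    cooccurrence: CooccurrenceTable,
    disease_layer: str,
    symptom_layer: str,
) -> tuple[list[str], np.ndarray, int]:
    d_idx = network.layer_index(disease_layer)
    disease_ids = network.layers[d_idx].node_ids
    shared = shared_symptom_counts(network, disease_layer, symptom_layer)
    nbrs = cooccurrence.neighbors()
    kept, diffs, dropped = [], [], 0
    for i, d in enumerate(disease_ids):
        co = np.array([other in nbrs.get(d, set()) for other in disease_ids])
        co[i] = False
        non = ~co
        non[i] = False
        if co.sum() == 0 or non.sum() == 0:
            dropped += 1
            continue
        kept.append(d)
        diffs.append(shared[i, co].mean() - shared[i, non].mean())
    return kept, np.asarray(diffs), dropped


def enrichment_ttest(
    network: MultiLayerNetwork,
    cooccurrence: CooccurrenceTable,
    disease_layer: str = "disease",
    symptom_layer: str = "symptom",
) -> EnrichmentResult:
    """Do co-occurring diseases share more symptoms than non-co-occurring ones?

    Per disease with at least one partner of each kind, take the difference of
    mean shared-symptom counts (co-occurring minus non-co-occurring); test the
    differences with a paired one-sided t (H1: mean difference > 0),
    df = retained diseases - 1. A zero-variance difference vector is reported
    as a degenerate result rather than an error.
    """
    kept, diffs, dropped = _enrichment_differences(
        network, cooccurrence, disease_layer, symptom_layer
    )
    n = len(kept)
    if n < 2:
        raise ValueError(f"need >= 2 retained diseases, have {n} ({dropped} dropped)")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        p = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
        return EnrichmentResult(t_stat, p, n - 1, sd, diffs, tuple(kept), dropped, degenerate=True)
    t_stat = mean / (sd / math.sqrt(n))
    p = float(t_dist.sf(t_stat, df=n - 1))
    return EnrichmentResult(float(t_stat), p, n - 1, sd, diffs, tuple(kept), dropped)


def enrichment_by_tier(
    network: MultiLayerNetwork,
    cooccurrence: CooccurrenceTable,
    thresholds: tuple[int, int] = (100, 10),
    disease_layer: str = "disease",
    symptom_layer: str = "symptom",
) -> dict[str, EnrichmentResult]:
    """Enrichment test per disease tier binned by associated-symptom count.

    Tier 1: >= ``thresholds[0]`` symptoms; tier 2: in between; tier 3:
    <= ``thresholds[1]``. Tiers with fewer than two retained diseases are
    omitted from the result.
    """
    hi, lo = thresholds
    if hi <= lo:
        raise ValueError("thresholds must be (high, low) with high > low")
    d_idx, _, inter = _disease_symptom_view(network, disease_layer, symptom_layer)
    disease_ids = network.layers[d_idx].node_ids
    n_symptoms = (inter > 0).sum(axis=1)
    kept, diffs, _ = _enrichment_differences(network, cooccurrence, disease_layer, symptom_layer)
    count_of = {d: int(n_symptoms[i]) for i, d in enumerate(disease_ids)}
    tiers = {"tier1": [], "tier2": [], "tier3": []}
    for d, diff in zip(kept, diffs):
        c = count_of[d]
        key = "tier1" if c >= hi else ("tier3" if c <= lo else "tier2")
        tiers[key].append((d, diff))
    out: dict[str, EnrichmentResult] = {
        "total": enrichment_ttest(network, cooccurrence, disease_layer, symptom_layer)
    }
    for key, entries in tiers.items():
        if len(entries) < 2:
            continue
        ids = tuple(d for d, _ in entries)
        dvec = np.array([x for _, x in entries])
        mean, sd, n = float(dvec.mean()), float(dvec.std(ddof=1)), len(dvec)
        if sd == 0.0:
            t_stat = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
            p = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
            out[key] = EnrichmentResult(t_stat, p, n - 1, sd, dvec, ids, 0, degenerate=True)
        else:
            t_stat = mean / (sd / math.sqrt(n))
            out[key] = EnrichmentResult(
                float(t_stat), float(t_dist.sf(t_stat, df=n - 1)), n - 1, sd, dvec, ids, 0
            )
    return out


def shared_symptom_report(
    network: MultiLayerNetwork,
    target_disease: str,
    scores: ScoreVector | np.ndarray,
    disease_layer: str = "disease",
    symptom_layer: str = "symptom",
) -> pd.DataFrame:
    """Rank diseases by score and report their shared-symptom count with the target.

    Columns (disease, shared_symptom_count, f); sorted by descending f, ties
    broken by disease id. The target itself is excluded.
    """
    d_idx = network.layer_index(disease_layer)
    disease_ids = network.layers[d_idx].node_ids
    if target_disease not in disease_ids:
        raise KeyError(f"unknown target disease {target_disease!r}")
    vals = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    if vals.size == network.total_size:
        vals = vals[network.layer_slice(d_idx)]
    if vals.size != len(disease_ids):
        raise ValueError("scores must cover the disease layer")
    shared = shared_symptom_counts(network, disease_layer, symptom_layer)
    ti = disease_ids.index(target_disease)
    rows = [
        {"disease": d, "shared_symptom_count": int(shared[ti, i]), "f": float(vals[i])}
        for i, d in enumerate(disease_ids)
        if i != ti
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["f", "disease"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
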