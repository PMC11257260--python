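"""AUC evaluation, the experiment matrix, aggregation, and sampler PCA.

One experiment cell is (network, sampler, predictor, run): the run fixes the
test split, the sampler fixes the observed training edges, the predictor
scores the balanced test pairs, and the AUC — the probability that a random
held-out edge outranks a random non-edge, ties counted one half — is the
recorded outcome.  Aggregation mirrors the domain-level summary tables
(mean +/- sd per domain x sampler x predictor), winner counting awards shared
wins on exact ties, and the PCA characterizes each sampler by its per-network
AUC profile for one predictor within one domain.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .graph_core import Graph
from .link_predictors import PredictorSpec, ScoreTable, score_pairs
from .missingness_samplers import SamplerSpec
from .protocol import (
    DEFAULT_CLASS_SIZE,
    balance_classes,
    make_split_bundle,
    sample_graph,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "network_id",
    "domain",
    "sampler",
    "predictor",
    "run_index",
    "auc",
    "achieved_sample_size",
)


@dataclass(frozen=True)
class ResultRecord:
    """One AUC observation for one experiment cell."""

    network_id: str
    domain: str
    sampler: str
    predictor: str
    run_index: int
    auc: float
    achieved_sample_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc={self.auc} outside [0, 1]")


@dataclass(frozen=True)
class SamplerProfile:
    """A sampler characterized by its per-network mean-AUC feature vector."""

    sampler: str
    feature_vector: tuple
    pc_scores: tuple  # first two principal-component coordinates


def compute_auc(pos_scores, neg_scores) -> float:
    """Rank-statistic AUC: [#(p > q) + 0.5 #(p = q)] / (|pos| |neg|).

    Equals the trapezoidal area under the ROC curve; computed via the
    Mann-Whitney U statistic with midranks for ties.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score multisets must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _cell_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) % (2**31), *key])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    networks: Sequence[tuple[str, Graph, str]],
    samplers: Sequence[SamplerSpec],
    predictors: Sequence[PredictorSpec],
    repeats: int = 5,
    master_seed: int = 0,
    class_size: int = DEFAULT_CLASS_SIZE,
    balanced_eval: bool = True,
    custom_scorers: dict[str, Callable] | None = None,
) -> tuple[list[ResultRecord], list[dict]]:
    """Run the full (network x run x sampler x predictor) matrix.

    Within one run on one network, the test edge/non-edge sets are shared by
    every sampler and predictor; within one sampler, the training sample is
    shared by every predictor.  All seeds derive deterministically from
    ``master_seed``.  Cells that raise are recorded as failures and the run
    continues.  Returns (records, failures).

    ``custom_scorers`` maps extra predictor names to callables
    ``f(sample, bundle, pairs, seed) -> ScoreTable`` (used for oracle/random
    reference predictors in validation).
    """
    records: list[ResultRecord] = []
    failures: list[dict] = []
    custom_scorers = custom_scorers or {}
    for ni, (net_id, graph, domain) in enumerate(networks):
        for run in range(repeats):
            run_seed = _cell_seed(master_seed, ni, run)
            for si, sampler in enumerate(samplers):
                spec = SamplerSpec(
                    sampler.name, dict(sampler.params),
                    _cell_seed(master_seed, ni, run, si),
                )
                try:
                    bundle = make_split_bundle(graph, spec, run_seed)
                    sample = sample_graph(bundle)
                    test_pos = sorted(bundle.Y)
                    test_neg = sorted(bundle.Y_tilde)
                    if balanced_eval:
                        test_pos, test_neg = balance_classes(
                            bundle.Y, bundle.Y_tilde, class_size, run_seed
                        )
                    unique_pairs = sorted(set(test_pos) | set(test_neg))
                except Exception as exc:  # sampler/split failure fails all predictors
                    for pred in predictors:
                        failures.append(
                            dict(network_id=net_id, sampler=sampler.name,
                                 predictor=pred.name, run_index=run, error=str(exc))
                        )
                    logger.warning("%s/%s run %d: %s", net_id, sampler.name, run, exc)
                    continue
                for pi, pred in enumerate(predictors):
                    pseed = _cell_seed(master_seed, ni, run, si, pi)
                    t0 = time.perf_counter()
                    try:
                        if pred.name in custom_scorers:
                            table: ScoreTable = custom_scorers[pred.name](
                                sample, bundle, unique_pairs, pseed
                            )
                        else:
                            table = score_pairs(
                                PredictorSpec(pred.name, dict(pred.params), pseed),
                                sample, bundle, unique_pairs,
                            )
                        auc = compute_auc(table.scores(test_pos), table.scores(test_neg))
                    except Exception as exc:
                        failures.append(
                            dict(network_id=net_id, sampler=sampler.name,
                                 predictor=pred.name, run_index=run, error=str(exc))
                        )
                        logger.warning(
                            "%s/%s/%s run %d failed: %s",
                            net_id, sampler.name, pred.name, run, exc,
                        )
                        continue
                    records.append(
                        ResultRecord(
                            net_id, domain, sampler.name, pred.name, run,
                            auc, len(bundle.E_sample),
                        )
                    )
                    logger.info(
                        "cell %s %s %s run=%d auc=%.4f sample=%d t=%.2fs",
                        net_id, sampler.name, pred.name, run, auc,
                        len(bundle.E_sample), time.perf_counter() - t0,
                    )
    return records, failures


def records_to_frame(records: Sequence[ResultRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=RESULT_COLUMNS)


def aggregate_by_domain(records) -> pd.DataFrame:
    """Mean and sd of AUC per (domain, sampler, predictor) cell.

    The standard deviation uses the population convention (ddof = 0), taken
    over all networks and runs within the cell.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    out = (
        df.groupby(["domain", "sampler", "predictor"])["auc"]
        .agg(mean_auc="mean", sd_auc=lambda s: float(np.std(s, ddof=0)), n_obs="size")
        .reset_index()
    )
    return out


def count_best_methods(aggregated: pd.DataFrame) -> dict[str, int]:
    """Winner counts per predictor over (domain, sampler) cells.

    The predictor with maximal mean AUC in a cell receives a win; exact ties
    award a shared win to every tied predictor.
    """
    wins: dict[str, int] = {p: 0 for p in aggregated["predictor"].unique()}
    for _, cell in aggregated.groupby(["domain", "sampler"]):
        best = cell["mean_auc"].max()
        for p in cell.loc[cell["mean_auc"] == best, "predictor"]:
            wins[p] += 1
    return wins


def pca_sampler_profiles(
    records,
    domain: str,
    predictor: str,
    scale: bool = False,
) -> list[SamplerProfile]:
    """PCA of sampler AUC-profiles within one domain for one predictor.

    Each sampler's feature vector holds its mean AUC (over runs) on every
    network of the domain; missing cells are imputed by the domain-predictor
    mean (logged).  Columns are centered (variance scaling optional) and the
    first two principal components are returned with a deterministic sign:
    each loading vector sums to a nonnegative value.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[(df["domain"] == domain) & (df["predictor"] == predictor)]
    if sub.empty:
        raise ValueError(f"no records for domain={domain!r} predictor={predictor!r}")
    pivot = (
        sub.groupby(["sampler", "network_id"])["auc"].mean().unstack("network_id")
    )
    if pivot.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samplers")
    if pivot.isna().any().any():
        logger.info(
            "imputing %d missing sampler/network cells by the domain mean",
            int(pivot.isna().sum().sum()),
        )
        pivot = pivot.fillna(float(np.nanmean(pivot.values)))

    X = pivot.values
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    k = min(2, min(Xc.shape) - 0) if min(Xc.shape) >= 2 else 1
    pca = PCA(n_components=min(k, 2), svd_solver="full")
    scores = pca.fit_transform(Xc)
    for j in range(pca.components_.shape[0]):
        if pca.components_[j].sum() < 0:
            pca.components_[j] = -pca.components_[j]
            scores[:, j] = -scores[:, j]
    if scores.shape[1] < 2:  # degenerate: a single usable direction
        scores = np.hstack([scores, np.zeros((scores.shape[0], 1))])
    return [
        SamplerProfile(s, tuple(map(float, X[i])), (float(scores[i, 0]), float(scores[i, 1])))
        for i, s in enumerate(pivot.index)
    ]
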