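"""Shared fixtures: tiny cohorts and a cached end-to-end pipeline run."""

import numpy as np
import pytest

from amogel.model import ModelConfig
from amogel.pipeline import ArmConfig, PipelineConfig, PriorTables, run_single_trial
from amogel.synthetic_data import (SimConfig, generate_multiomics,
                                   generate_prior_tables, make_worked_example)


@pytest.fixture(scope="session")
def worked_example():
    """Fixed 12-sample, 8-feature, 2-class cohort with hand-checkable values."""
    return make_worked_example()


def small_sim_config(seed: int = 11) -> SimConfig:
    """A reduced cohort for fast pipeline-level tests."""
    return SimConfig(n_samples_per_class=20, n_features=(30, 20, 10),
                     n_planted_per_class=3, effect_size=3.0, prior_overlap=0.5,
                     n_decoy_ppi=10, n_decoy_terms=3, seed=seed)


def fast_pipeline_config(epochs: int = 30, seed_independent: bool = True) -> PipelineConfig:
    """Pipeline settings scaled to the small synthetic cohorts."""
    return PipelineConfig(
        anova_k={"mRNA": 12, "methylation": 8, "miRNA": "all"},
        arm=ArmConfig(k=80, max_antecedent_len=3),
        model=ModelConfig(hidden_dim=16, heads=4, epochs=epochs, lr=0.01),
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_sim_config()
    matrices, labels, gt = generate_multiomics(cfg)
    ppi, kegg, go = generate_prior_tables(cfg, gt)
    return {"sim": cfg, "matrices": matrices, "labels": labels, "gt": gt,
            "priors": PriorTables(ppi, kegg, go)}


@pytest.fixture(scope="session")
def small_trial(small_cohort):
    """One full pipeline run on the small cohort, shared across tests."""
    cfg = fast_pipeline_config()
    return cfg, run_single_trial(small_cohort["matrices"], small_cohort["labels"],
                                 cfg, seed=1, priors=small_cohort["priors"])


def random_transaction_db(rng: np.random.Generator, max_items: int = 12,
                          max_transactions: int = 30):
    """Random small TransactionDB for oracle comparisons."""
    from amogel.arm import Item, TransactionDB

    n_items = int(rng.integers(2, max_items + 1))
    n_trans = int(rng.integers(2, max_transactions + 1))
    items = [Item(f"g{i}", int(rng.integers(0, 3))) for i in range(n_items)]
    density = rng.uniform(0.2, 0.8)
    transactions = []
    for _ in range(n_trans):
        mask = rng.random(n_items) < density
        if not mask.any():
            mask[int(rng.integers(0, n_items))] = True
        transactions.append(frozenset(it for it, m in zip(items, mask) if m))
    return TransactionDB("c", transactions)


def brute_force_closed_itemsets(db, min_support: float):
    """Independent oracle: enumerate all 2^n subsets and apply the closure test."""
    from itertools import combinations

    items = sorted({it for t in db.transactions for it in t})
    n = len(db.transactions)
    freq = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            cnt = sum(1 for t in db.transactions if s <= t)
            if cnt >= min_support * n - 1e-9 and cnt > 0:
                freq[s] = cnt
    closed = {}
    for s, cnt in freq.items():
        # closed iff no superset in the full lattice has equal support;
        # an equal-support superset is itself frequent, so freq suffices
        if not any(s < t and c == cnt for t, c in freq.items()):
            closed[s] = cnt / n
    return closed
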