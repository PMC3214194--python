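"""Synthetic data generators.

Real input to the inference pipeline is a preprocessed (log-intensity)
expression matrix from a microarray experiment.  For testing and
benchmarking without downloads, :func:`simulate_expression` plants
co-expression modules with a single-factor linear model: every gene in a
module is a noisy multiple of one latent per-sample factor, so module
members are strongly mutually dependent while genes from different modules
(and pure-noise genes) are independent.  The generator does not emulate
probe effects, batch effects or heavy-tailed microarray noise — it provides
a known ground truth that a dependency-based inference method should
recover.

Defaults: 50 samples, 3 modules of 10 genes, 10 noise genes, loading 2.0,
noise standard deviation 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidSpecError
from .inference import ExpressionMatrix

__all__ = [
    "SyntheticDesign",
    "simulate_expression",
    "random_weighted_network",
    "module_recovery_metrics",
]


@dataclass
class SyntheticDesign:
    """Parameters of the planted-module generator.

    loading is the coefficient tying a module gene to its latent factor;
    noise_sd the standard deviation of the per-gene Gaussian noise.  With
    the defaults the within-module correlation is
    loading^2 / (loading^2 + noise_sd^2) ≈ 0.94.
    """

    n_samples: int = 50
    n_modules: int = 3
    genes_per_module: int = 10
    n_noise_genes: int = 10
    loading: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_modules, self.genes_per_module) < 1:
            raise InvalidSpecError("sample/module/gene counts must be positive")
        if self.n_noise_genes < 0:
            raise InvalidSpecError("n_noise_genes must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")


def simulate_expression(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Generate an expression matrix with planted co-expression modules.

    One latent standard-normal factor per module per sample; each module
    gene is ``loading * factor + Normal(0, noise_sd)``; noise genes are
    pure Normal(0, 1).  Returns the matrix and the ground-truth labels
    (module index per gene, -1 for noise genes).
    """
    rng = np.random.default_rng(design.seed)
    n, k, gpm = design.n_samples, design.n_modules, design.genes_per_module
    factors = rng.standard_normal((n, k))
    module_genes = np.repeat(factors, gpm, axis=1) * design.loading
    module_genes += rng.normal(0.0, design.noise_sd, size=module_genes.shape)
    noise_genes = rng.standard_normal((n, design.n_noise_genes))
    values = np.hstack([module_genes, noise_genes])

    probeset_ids = [f"M{m}G{i:02d}" for m in range(k) for i in range(gpm)]
    probeset_ids += [f"NOISE{i:02d}" for i in range(design.n_noise_genes)]
    labels = {pid: m for m, pid in zip(np.repeat(np.arange(k), gpm), probeset_ids)}
    labels.update({pid: -1 for pid in probeset_ids[k * gpm:]})

    x = ExpressionMatrix(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        probeset_ids=probeset_ids,
        values=values,
    )
    return x, labels


def module_recovery_metrics(result, labels: dict[str, int]) -> dict[str, float]:
    """Score how well inferred weights recover the planted modules.

    Gene pairs are split into within-module (same module label >= 0) and
    between-module (different modules, or involving a noise gene).  Returns
    the two mean weights and the AUC of ranking all pairs by weight, i.e.
    the probability that a random within pair outweighs a random between
    pair (ties count 1/2, Mann-Whitney convention).
    """
    ids = result.probeset_ids
    w = np.asarray(result.weights)
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            li, lj = labels[ids[i]], labels[ids[j]]
            (within if li == lj and li >= 0 else between).append(w[i, j])
    within = np.array(within)
    between = np.array(between)
    from scipy.stats import rankdata

    pooled = np.concatenate([within, between])
    ranks = rankdata(pooled)
    u = ranks[: len(within)].sum() - len(within) * (len(within) + 1) / 2
    auc = u / (len(within) * len(between))
    return {
        "within_mean": float(within.mean()),
        "between_mean": float(between.mean()),
        "auc": float(auc),
        "n_within": int(len(within)),
        "n_between": int(len(between)),
    }


def random_weighted_network(n_nodes: int, edge_prob: float, seed: int = 0) -> nx.Graph:
    """Erdős–Rényi topology with uniform(0, 1] edge weights, fully seeded."""
    if not 0 <= edge_prob <= 1:
        raise InvalidSpecError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                g.add_edge(ids[i], ids[j], weight=float(1.0 - rng.random()))
    return g
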