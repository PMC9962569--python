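"""Hybrid swarm → SGD training of the super-resolution network.

The swarm searches the network's flat parameter space with the training MSE
on a fixed fitness subset of patches as objective; the best particle found
becomes the initialization for plain SGD, which refines on the full patch
set.  The point of the hybrid is a better-than-random starting position for
a non-convex problem that gradient descent alone enters blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .network import (NetworkSpec, ParameterVector, SRNetwork, build_network,
                      flatten, mse_cost, sgd_step, unflatten)
from .swarm import SwarmConfig, minimize

__all__ = ["HybridConfig", "TrainingReport", "swarm_pretrain", "train_hybrid",
           "desk_split"]


def desk_split(corpus_seed: int = 7, n_images: int = 16, size: int = 64,
               scale: int = 2, lr_patch: int = 8, train_stride: int = 6):
    """Deterministic desk-scale experiment: patches and held-out pairs.

    Every fourth image is held out for evaluation (so each content kind is
    represented on both sides); the rest supply overlapping training
    patches.  Returns ``(train_batch, eval_batch, held_out_pairs)``.
    """
    from .data import (CorpusSpec, concat_batches, extract_patch_pairs,
                       generate_corpus, make_pair)
    corpus = generate_corpus(CorpusSpec(n_images=n_images, size=size,
                                        seed=corpus_seed))
    pairs = [make_pair(im, scale) for im in corpus]
    eval_idx = set(range(3, n_images, 4))
    train = concat_batches([extract_patch_pairs(pairs[i], lr_patch,
                                                train_stride)
                            for i in range(n_images) if i not in eval_idx])
    evalb = concat_batches([extract_patch_pairs(pairs[i], lr_patch, lr_patch)
                            for i in sorted(eval_idx)])
    return train, evalb, [pairs[i] for i in sorted(eval_idx)]


def _default_swarm() -> SwarmConfig:
    # reference scale: 50 particles, 10,000 iterations, sweep every 100
    return SwarmConfig(n_particles=50, eval_budget=None, max_iterations=10_000,
                       mutation_period=100, algorithm="smcpso")


@dataclass(frozen=True)
class HybridConfig:
    swarm: SwarmConfig = field(default_factory=_default_swarm)
    sgd_lr: float = 1e-4
    sgd_epochs: int = 25
    #: heavy-ball momentum of the SGD phase (0 disables it)
    sgd_momentum: float = 0.9
    #: optional ((lr, epochs), ...) phases overriding sgd_lr/sgd_epochs
    sgd_schedule: tuple | None = None
    sgd_batch_size: int = 16
    #: patch pairs held fixed as the swarm fitness set
    fitness_subset: int = 64
    seed: int = 0

    @property
    def phases(self) -> tuple:
        return (self.sgd_schedule if self.sgd_schedule is not None
                else ((self.sgd_lr, self.sgd_epochs),))


@dataclass
class TrainingReport:
    """Per-epoch trajectory plus provenance of both phases."""

    provenance: str                 # "hybrid" or "sgd-only"
    swarm_seed: int
    sgd_seed: int
    pretrain_fitness: float | None  # swarm-phase best fitness (None if skipped)
    epochs: list = field(default_factory=list)  # dicts per epoch

    @property
    def final_eval_mse(self) -> float:
        return self.epochs[-1]["eval_loss"] if self.epochs else float("nan")


def _subset(batch, n):
    from .data import TrainingBatch
    n = min(n, len(batch))
    return TrainingBatch(lr=batch.lr[:n], hr=batch.hr[:n],
                         scale_factor=batch.scale_factor,
                         offsets=batch.offsets[:n])


def swarm_pretrain(spec: NetworkSpec, batch,
                   config: HybridConfig) -> ParameterVector:
    """Best network parameter vector found by swarm search.

    Fitness is the MSE cost on a fixed subset of ``batch``; search bounds
    are ±3 He-sigmas per layer.  Each particle starts as an independently
    seeded network initialization — a valid, trainable set of weights and
    biases — with particle 0 being exactly the initialization plain SGD
    would start from, so by elitism the returned vector's fitness is never
    worse than that baseline's, nor than any particle of iteration 0.
    """
    if len(batch) == 0:
        raise ValueError("empty training batch")
    template = build_network(spec, init_seed=config.seed)
    dim = template.n_parameters
    lower, upper = template.search_bounds()
    fitness_set = _subset(batch, config.fitness_subset)

    def objective(x):
        x = np.atleast_2d(x)
        vals = np.empty(x.shape[0])
        for i, row in enumerate(x):
            unflatten(template, row)
            vals[i] = mse_cost(template, fitness_set)
        return vals

    swarm_cfg = replace(config.swarm, seed=config.seed)
    init = np.stack([flatten(build_network(spec, config.seed + k)).values
                     for k in range(swarm_cfg.n_particles)])
    result = minimize(objective, lower, upper, dim, swarm_cfg,
                      init_positions=init)
    return ParameterVector(values=result.best_position,
                           layout=template.layout)


def _patch_metrics(net: SRNetwork, batch) -> tuple[float, float, float]:
    """(eval MSE cost, mean PSNR dB, mean global SSIM) on a patch stack."""
    out = net.forward(batch.lr)
    n = out.shape[0]
    cost = float(np.sum((out - batch.hr) ** 2) / n)
    psnrs = [metrics.psnr(255 * np.clip(out[i, 0], 0, 1), 255 * batch.hr[i, 0])
             for i in range(n)]
    ssims = [metrics.ssim(255 * np.clip(out[i, 0], 0, 1), 255 * batch.hr[i, 0])
             for i in range(n)]
    return cost, float(np.mean(psnrs)), float(np.mean(ssims))


def train_hybrid(spec: NetworkSpec, train_batch, eval_batch,
                 config: HybridConfig,
                 pretrain: bool = True) -> tuple[TrainingReport, SRNetwork]:
    """Swarm-initialized (or plain) SGD training with a per-epoch report.

    With ``pretrain=False`` the network starts from its seeded random
    initialization — the SGD-alone baseline with an identical gradient
    budget.  ``sgd_epochs=0`` returns the initialization unchanged.
    """
    if len(train_batch) == 0 or len(eval_batch) == 0:
        raise ValueError("train and eval batches must be nonempty")
    from .data import TrainingBatch

    net = build_network(spec, init_seed=config.seed)
    pre_fit = None
    if pretrain:
        vec = swarm_pretrain(spec, train_batch, config)
        unflatten(net, vec)
        pre_fit = mse_cost(net, _subset(train_batch, config.fitness_subset))

    report = TrainingReport(provenance="hybrid" if pretrain else "sgd-only",
                            swarm_seed=config.seed, sgd_seed=config.seed + 1,
                            pretrain_fitness=pre_fit)
    rng = np.random.default_rng(config.seed + 1)
    n = len(train_batch)
    bs = min(config.sgd_batch_size, n)
    momentum = np.zeros(net.n_parameters)
    from .network import flatten, mse_cost_grad
    for alpha, n_epochs in config.phases:
        for _ in range(n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n - bs + 1, bs):
                sel = order[start:start + bs]
                mb = TrainingBatch(lr=train_batch.lr[sel],
                                   hr=train_batch.hr[sel],
                                   scale_factor=train_batch.scale_factor,
                                   offsets=train_batch.offsets[sel])
                if config.sgd_momentum > 0:
                    cost, grad = mse_cost_grad(net, mb)
                    momentum = config.sgd_momentum * momentum + grad
                    unflatten(net, flatten(net).values - alpha * momentum)
                    losses.append(cost)
                else:
                    losses.append(sgd_step(net, mb, alpha))
            eval_loss, psnr_db, ssim_val = _patch_metrics(net, eval_batch)
            report.epochs.append({
                "train_loss": float(np.mean(losses)), "eval_loss": eval_loss,
                "psnr_db": psnr_db, "ssim": ssim_val})
    return report, net
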