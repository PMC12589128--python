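"""Per-nucleotide attribution and in-silico saturation mutagenesis.

Contribution scores are expected gradients: integrated gradients from
each of ``n_background`` mononucleotide-preserving shuffles of the input
sequence to the input itself, averaged over backgrounds.  The class logit
is attributed, so the completeness identity

    sum(actual) ~= logit(x) - mean_b logit(background_b)

holds up to the Riemann discretization of the path integral.
``hypothetical`` projects the attribution onto all four bases per
position (background-corrected); ``actual`` is the hypothetical score
masked to the observed base.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Sequential


@dataclass
class AttributionTrack:
    actual: np.ndarray  # 4 x L, zero off the observed base
    hypothetical: np.ndarray  # 4 x L
    class_index: int
    n_background: int


def shuffle_sequence(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mononucleotide-preserving shuffle of a one-hot sequence (columns permuted)."""
    return x[:, rng.permutation(x.shape[1])]


def contribution_scores(
    model: Sequential,
    x: np.ndarray,
    class_index: int,
    n_background: int = 100,
    n_steps: int = 24,
    seed: int = 0,
) -> AttributionTrack:
    """Expected-gradients attribution of one class logit for one sequence.

    For each shuffled background b the gradient of the class logit is
    averaged along the straight path from b to x (midpoint rule,
    ``n_steps`` points) and multiplied by (x - b).  Backgrounds are then
    averaged.  Gradients are batched across steps for speed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    L = x.shape[1]
    backgrounds = np.stack([shuffle_sequence(x, rng) for _ in range(n_background)])
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    hyp = np.zeros((4, L))
    for b in backgrounds:
        path = b[None] + alphas[:, None, None] * (x - b)[None]
        grad = model.input_gradient(path, class_index)  # (n_steps, 4, L)
        gbar = grad.mean(axis=0)
        # background-corrected projection onto each candidate base
        corr = (b * gbar).sum(axis=0, keepdims=True)
        hyp += gbar - corr
    hyp /= n_background
    actual = hyp * x
    return AttributionTrack(actual=actual, hypothetical=hyp,
                            class_index=class_index, n_background=n_background)


def completeness_gap(
    model: Sequential, x: np.ndarray, track: AttributionTrack,
    backgrounds: np.ndarray | None = None, seed: int = 0,
) -> tuple[float, float]:
    """(sum of actual attributions, logit difference) for the completeness check."""
    rng = np.random.default_rng(seed)
    if backgrounds is None:
        backgrounds = np.stack(
            [shuffle_sequence(x, rng) for _ in range(track.n_background)]
        )
    fx = model.forward(x[None], train=False)[0, track.class_index]
    fb = model.forward(backgrounds, train=False)[:, track.class_index].mean()
    return float(track.actual.sum()), float(fx - fb)


def saturation_mutagenesis(
    model: Sequential, x: np.ndarray, class_index: int, batch_size: int = 256
) -> np.ndarray:
    """Delta class logit for every single-base substitution.

    ``delta[b, p]`` is the logit of the sequence with position p set to
    base b minus the reference logit; reference-base entries are exactly
    zero.
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[1]
    ref = float(model.forward(x[None], train=False)[0, class_index])
    variants = []
    coords = []
    for p in range(L):
        for b in range(4):
            if x[b, p] == 1.0:
                continue
            v = x.copy()
            v[:, p] = 0.0
            v[b, p] = 1.0
            variants.append(v)
            coords.append((b, p))
    delta = np.zeros((4, L))
    for i in range(0, len(variants), batch_size):
        batch = np.stack(variants[i : i + batch_size])
        out = model.forward(batch, train=False)[:, class_index]
        for (b, p), val in zip(coords[i : i + batch_size], out):
            delta[b, p] = val - ref
    return delta
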