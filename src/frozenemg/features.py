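"""Frozen random multi-scale dilated convolution features.

Two structurally identical branches — one fed the raw (filtered) segment,
one the selected-IMF segment — each apply three parallel 1-D convolution
modules with kernel/dilation pairs (3,1), (5,3), (11,8) and 256 filters.
Weights are drawn once from the Kaiming-normal distribution
N(0, 2/(C_in*k)), biases are zero, and everything is frozen: feature
extraction never mutates state.  Each module's ReLU activation map is
summarised per filter by global average pooling (GAP, the temporal mean)
and the proportion of positive values (PPV), giving 512 values per
module, 1536 per branch and a fused 3072-dimensional vector at defaults.

Fixed feature ordering (the on-disk contract): within a module the GAP
block precedes the PPV block; modules appear in configuration order; the
raw branch precedes the IMF branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_MODULE_CONFIGS: tuple[tuple[int, int], ...] = ((3, 1), (5, 3), (11, 8))


@dataclass(frozen=True)
class ConvModuleSpec:
    """One frozen dilated-convolution module."""

    kernel_len: int
    dilation: int
    weights: np.ndarray        # n_filters x C_in x k, read-only
    biases: np.ndarray         # n_filters, read-only

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def padding(self) -> int:
        return self.dilation * (self.kernel_len - 1) // 2

    @property
    def n_params(self) -> int:
        """Frozen parameter count: weights plus biases."""
        return self.weights.size + self.biases.size


@dataclass(frozen=True)
class ConvBank:
    """The dual-branch bank: same architecture, independent weights."""

    raw_modules: tuple[ConvModuleSpec, ...]
    imf_modules: tuple[ConvModuleSpec, ...]
    seed: int
    configs: tuple[tuple[int, int], ...]

    @property
    def n_params(self) -> int:
        return sum(m.n_params for m in self.raw_modules + self.imf_modules)

    @property
    def feature_dim(self) -> int:
        return 2 * sum(2 * m.n_filters
                       for m in self.raw_modules)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.size


def _draw_module(cfg: tuple[int, int], n_filters: int, in_channels: int,
                 rng: np.random.Generator) -> ConvModuleSpec:
    k, d = cfg
    if k % 2 == 0:
        raise ValueError(f"kernel length {k} must be odd for exact "
                         "same-padding")
    sd = np.sqrt(2.0 / (in_channels * k))
    w = rng.normal(0.0, sd, size=(n_filters, in_channels, k))
    b = np.zeros(n_filters)
    w.setflags(write=False)
    b.setflags(write=False)
    return ConvModuleSpec(kernel_len=k, dilation=d, weights=w, biases=b)


def init_conv_bank(configs: Sequence[tuple[int, int]] = DEFAULT_MODULE_CONFIGS,
                   n_filters: int = 256, in_channels: int = 10,
                   seed: int = 0) -> ConvBank:
    """Draw both branches from one seeded stream and freeze them.

    The raw branch's modules are drawn first, then the IMF branch's, so a
    single integer reproduces the whole bank.
    """
    rng = np.random.default_rng(seed)
    raw = tuple(_draw_module(c, n_filters, in_channels, rng) for c in configs)
    imf = tuple(_draw_module(c, n_filters, in_channels, rng) for c in configs)
    return ConvBank(raw_modules=raw, imf_modules=imf, seed=seed,
                    configs=tuple(tuple(c) for c in configs))


def conv_forward(spec: ConvModuleSpec, segment: np.ndarray) -> np.ndarray:
    """Dilated multi-channel cross-correlation, bias, ReLU; same padding.

    Output position i of filter j is
    ReLU(b_j + sum_c sum_t w[j,c,t] * x[c, i + (t - (k-1)/2) * d]) with
    zeros outside the segment, so the output length equals the input
    length exactly.
    """
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    if x.shape[0] != spec.in_channels:
        raise ValueError(
            f"segment has {x.shape[0]} channels, module expects "
            f"{spec.in_channels}"
        )
    L = x.shape[1]
    pad = spec.padding
    xp = np.zeros((x.shape[0], L + 2 * pad))
    xp[:, pad:pad + L] = x
    out = np.broadcast_to(spec.biases[:, None],
                          (spec.n_filters, L)).copy()
    for t in range(spec.kernel_len):
        start = t * spec.dilation
        out += spec.weights[:, :, t] @ xp[:, start:start + L]
    np.maximum(out, 0.0, out=out)
    return out


def gap_ppv(activations: np.ndarray) -> np.ndarray:
    """Per-filter GAP (temporal mean) then PPV (fraction strictly > 0)."""
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    gap = a.mean(axis=1)
    ppv = np.count_nonzero(a > 0, axis=1) / a.shape[1]
    return np.concatenate([gap, ppv])


def _branch_features(modules: Sequence[ConvModuleSpec],
                     segment: np.ndarray) -> np.ndarray:
    return np.concatenate([gap_ppv(conv_forward(m, segment))
                           for m in modules])


def extract_features(bank: ConvBank, raw_seg: np.ndarray,
                     imf_seg: np.ndarray) -> FeatureVector:
    """Fuse both branches into the fixed-length feature vector."""
    raw_seg = np.atleast_2d(np.asarray(raw_seg, dtype=float))
    imf_seg = np.atleast_2d(np.asarray(imf_seg, dtype=float))
    if raw_seg.shape != imf_seg.shape:
        raise ValueError("raw and IMF segments must share a shape")
    values = np.concatenate([
        _branch_features(bank.raw_modules, raw_seg),
        _branch_features(bank.imf_modules, imf_seg),
    ])
    return FeatureVector(values=values)


def extract_matrix(bank: ConvBank, raw_segs: Sequence[np.ndarray],
                   imf_segs: Sequence[np.ndarray]) -> np.ndarray:
    """Stack feature vectors for a list of segments into an n x d matrix."""
    if len(raw_segs) != len(imf_segs):
        raise ValueError("need one IMF segment per raw segment")
    return np.vstack([
        extract_features(bank, r, i).values
        for r, i in zip(raw_segs, imf_segs)
    ])


def feature_mask(bank: ConvBank, stat: str) -> np.ndarray:
    """Boolean mask selecting the GAP or PPV entries of the fused vector.

    ``stat`` is "gap", "ppv" or "gap+ppv" (everything).
    """
    if stat == "gap+ppv":
        return np.ones(bank.feature_dim, dtype=bool)
    if stat not in ("gap", "ppv"):
        raise ValueError(f"unknown statistic '{stat}'")
    mask = np.zeros(bank.feature_dim, dtype=bool)
    pos = 0
    for module in bank.raw_modules + bank.imf_modules:
        nf = module.n_filters
        if stat == "gap":
            mask[pos:pos + nf] = True
        else:
            mask[pos + nf:pos + 2 * nf] = True
        pos += 2 * nf
    return mask
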