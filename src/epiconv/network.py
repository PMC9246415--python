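"""Allele–peptide pair fusion and the residual convolutional scorer.

The encoded MHC-II subtype head (1 x dim) is stacked on top of the 25 x dim
peptide embedding, giving a 26 x dim matrix per pair.  A stack of residual
one-dimensional convolution blocks ("BlockConv") with interleaved pooling
reads the matrix along the sequence axis; global pooling and a dense
sigmoid head turn the aggregate features into a presentation (or
immunogenicity) probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, conv1d_same, pool1d
from .alleles import (
    EMBED_DIM,
    HierarchicalEncoder,
    HlaAllele,
    OneHotEncoder,
    parse_allele,
    tokenize_layers,
)
from .norm import make_normalizer
from .peptides import PeptideVocab, validate_peptide

__all__ = [
    "BlockConvConfig",
    "ScorerConfig",
    "EncodedPair",
    "fuse_pair",
    "conv1d",
    "Conv1dLayer",
    "BlockConvNet",
    "PairScorer",
]


@dataclass
class BlockConvConfig:
    """Hyperparameters of the convolutional trunk."""

    n_blocks: int = 3
    channels: int = 128
    kernel_size: int = 3
    pooling: str = "both"  # {max, average, both}
    loss: str = "bce"  # {bce, mse}
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (same-padding)")
        if self.pooling not in ("max", "average", "both"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.loss not in ("bce", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class ScorerConfig:
    """Full pair-scorer configuration: encoders plus trunk.

    ``encoding`` selects the HLA representation (hierarchical, the one-hot
    ablation baseline, or none for the no-HLA control); ``norm`` the
    layer-matrix normalization; ``layer_fusion`` how the three nomenclature
    layers collapse to the head vector; ``pair_fusion`` how head and
    peptide combine (concat -> 26 rows, add -> head added to every row).
    """

    dim: int = EMBED_DIM
    encoding: str = "hierarchical"  # {hierarchical, one-hot, none}
    norm: str = "hlan"  # {hlan, batch, layer, none}
    layer_fusion: str = "concat"  # {add, concat, shared-concat}
    pair_fusion: str = "concat"  # {concat, add}
    architecture: str = "blockconv"  # {blockconv, plain}
    blockconv: BlockConvConfig = field(default_factory=BlockConvConfig)
    seed: int = 0

    def __post_init__(self):
        if self.encoding not in ("hierarchical", "one-hot", "none"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.pair_fusion not in ("concat", "add"):
            raise ValueError(f"unknown pair fusion {self.pair_fusion!r}")
        if self.architecture not in ("blockconv", "plain"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class EncodedPair:
    """The fused 26 x dim matrix for one (allele, peptide) pair."""

    ROWS = 26

    def __init__(self, matrix: np.ndarray, allele: str, peptide: str):
        matrix = np.asarray(matrix)
        if matrix.shape[0] != self.ROWS:
            raise ValueError(f"expected {self.ROWS} rows, got {matrix.shape[0]}")
        self.matrix = matrix
        self.allele = allele
        self.peptide = peptide


def fuse_pair(head: Tensor, pep: Tensor, mode: str = "concat") -> Tensor:
    """Combine head (B, dim) with peptide matrix (B, 25, dim).

    concat: head becomes row 0 of a (B, 26, dim) matrix; add: the head is
    added to every peptide row, keeping 25 rows.
    """
    if head.ndim != 2 or pep.ndim != 3:
        raise ValueError("expected batched head (B, dim) and peptide (B, 25, dim)")
    if head.shape[0] != pep.shape[0] or head.shape[1] != pep.shape[2]:
        raise ValueError(
            f"head {head.shape} incompatible with peptide {pep.shape}"
        )
    if mode == "concat":
        row = head.reshape(head.shape[0], 1, head.shape[1])
        return concat([row, pep], axis=1)
    if mode == "add":
        return pep + head.reshape(head.shape[0], 1, head.shape[1])
    raise ValueError(f"unknown pair fusion {mode!r}")


def conv1d(x: Tensor, kernel: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded 1-D convolution along axis 1 of (B, L, C_in).

    ``kernel`` has shape (K, C_in, C_out): for each output position t,
    out[t] = sum_k sum_c kernel[k, c, :] * x[t + k - K//2, c] — the
    channel-summed decomposition of a one-dimensional convolution.
    """
    return conv1d_same(x, kernel, bias)


def avgpool1d(x: Tensor, width: int, stride: int) -> Tensor:
    return pool1d(x, width, stride, kind="average")


class Conv1dLayer:
    """Trainable same-padded convolution with He-scaled init."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng):
        scale = np.sqrt(2.0 / (kernel_size * c_in))
        self.kernel = Tensor(
            rng.standard_normal((kernel_size, c_in, c_out)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.kernel, self.bias)

    def params(self) -> list[Tensor]:
        return [self.kernel, self.bias]


class BlockConvNet:
    """Residual convolution trunk + pooling + dense sigmoid head.

    Each block computes ``x + conv2(relu(conv1(x)))`` (an identity skip in
    the ResNet pattern); a width-2 stride-2 pooling layer follows every
    block, alternating max and average when pooling="both".  The trunk ends
    in global pooling over the remaining sequence positions and a dense
    sigmoid unit.  architecture="plain" drops the skip connections,
    keeping depth identical — the ablation comparator.
    """

    def __init__(
        self,
        config: BlockConvConfig,
        in_channels: int,
        residual: bool = True,
    ):
        self.config = config
        self.residual = residual
        rng = np.random.default_rng(config.seed)
        C = config.channels
        self.in_proj = (
            Conv1dLayer(in_channels, C, 1, rng) if in_channels != C else None
        )
        self.blocks = [
            (
                Conv1dLayer(C, C, config.kernel_size, rng),
                Conv1dLayer(C, C, config.kernel_size, rng),
            )
            for _ in range(config.n_blocks)
        ]
        head_in = 2 * C if config.pooling == "both" else C
        self.w_out = Tensor(
            rng.standard_normal((head_in, 1)) / np.sqrt(head_in),
            requires_grad=True,
        )
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

    def _pool(self, x: Tensor, i: int) -> Tensor:
        kind = self.config.pooling
        if kind == "both":
            kind = "max" if i % 2 == 0 else "average"
        if kind == "max":
            return pool1d(x, 2, 2, kind="max")
        return pool1d(x, 2, 2, kind="average")

    def forward(self, x: Tensor) -> Tensor:
        """(B, L, dim) pair matrices -> (B,) probabilities in (0, 1)."""
        if self.in_proj is not None:
            x = self.in_proj(x)
        for i, (c1, c2) in enumerate(self.blocks):
            h = c2(c1(x).relu())
            x = (x + h) if self.residual else h
            if x.shape[1] >= 2:
                x = self._pool(x, i)
        if self.config.pooling == "both":
            feat = concat([x.max(axis=1), x.mean(axis=1)], axis=1)
        elif self.config.pooling == "max":
            feat = x.max(axis=1)
        else:
            feat = x.mean(axis=1)
        logit = feat @ self.w_out + self.b_out
        return logit.sigmoid().reshape(logit.shape[0])

    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.in_proj is not None:
            ps += self.in_proj.params()
        for c1, c2 in self.blocks:
            ps += c1.params() + c2.params()
        ps += [self.w_out, self.b_out]
        return ps


class PairScorer:
    """End-to-end scorer: encoders, normalization, fusion and trunk.

    One architecture serves both the presentation and the immunogenicity
    task; only the training data differ.
    """

    def __init__(self, config: ScorerConfig, alleles: list[HlaAllele] | None = None):
        self.config = config
        self.vocab = PeptideVocab(dim=config.dim, seed=config.seed)
        self.encoder = None
        self.normalizer = None
        if config.encoding == "hierarchical":
            self.encoder = HierarchicalEncoder(
                dim=config.dim,
                fusion_mode=config.layer_fusion,
                seed=config.seed + 1,
            )
            self.normalizer = make_normalizer(config.norm, dim=config.dim)
        elif config.encoding == "one-hot":
            if not alleles:
                raise ValueError("one-hot encoding needs the allele inventory")
            self.encoder = OneHotEncoder(alleles, dim=config.dim, seed=config.seed + 1)
        self.net = BlockConvNet(
            config.blockconv,
            in_channels=config.dim,
            residual=(config.architecture == "blockconv"),
        )
        self.training = False

    # -- mode -----------------------------------------------------------------
    def train_mode(self, on: bool = True):
        self.training = on
        if self.normalizer is not None and hasattr(self.normalizer, "training"):
            self.normalizer.training = on
        return self

    # -- forward --------------------------------------------------------------
    def encode_heads(self, alleles: list[HlaAllele]) -> Tensor | None:
        if self.config.encoding == "none":
            return None
        if self.config.encoding == "one-hot":
            return self.encoder.head(alleles)
        tokens = np.array([tokenize_layers(a) for a in alleles])
        return self.encoder.head(tokens, normalizer=self.normalizer)

    def forward(self, alleles: list[HlaAllele], peptides: list[str]) -> Tensor:
        pep = self.vocab.embed(peptides)
        head = self.encode_heads(alleles)
        if head is None:
            x = pep
        else:
            x = fuse_pair(head, pep, mode=self.config.pair_fusion)
        return self.net.forward(x)

    def encode_pair(self, allele: HlaAllele, peptide: str) -> EncodedPair:
        """The fused input matrix for one pair (concat fusion only)."""
        if self.config.pair_fusion != "concat" or self.config.encoding == "none":
            raise ValueError("EncodedPair is defined for concat fusion with a head")
        pep = self.vocab.embed([peptide])
        head = self.encode_heads([allele])
        x = fuse_pair(head, pep, mode="concat")
        return EncodedPair(x.data[0], str(allele), peptide)

    # -- losses ---------------------------------------------------------------
    def loss(self, probs: Tensor, labels: np.ndarray) -> Tensor:
        y = np.asarray(labels, dtype=float)
        if self.config.blockconv.loss == "mse":
            d = probs - y
            return (d * d).mean()
        eps = 1e-12
        p = probs
        return -(
            Tensor(y) * (p + eps).log() + Tensor(1.0 - y) * (1.0 - p + eps).log()
        ).mean()

    # -- batched prediction ---------------------------------------------------
    def predict_batch(
        self, records, batch_size: int = 256
    ) -> "list[dict]":
        """Score (allele, peptide) records; bad records yield error entries.

        ``records`` is an iterable of (allele_str, peptide_str) pairs or a
        DataFrame with columns allele, peptide.  Returns a list of dicts
        with keys allele, peptide, score, error (order-preserving).
        """
        import pandas as pd

        if isinstance(records, pd.DataFrame):
            pairs = list(zip(records["allele"], records["peptide"]))
        else:
            pairs = list(records)
        out: list[dict] = [None] * len(pairs)
        valid: list[tuple[int, HlaAllele, str]] = []
        for i, (a, p) in enumerate(pairs):
            try:
                allele = parse_allele(str(a))
                validate_peptide(str(p))
                valid.append((i, allele, str(p)))
            except ValueError as exc:
                out[i] = {"allele": a, "peptide": p, "score": None,
                          "error": str(exc)}
        self.train_mode(False)
        for s in range(0, len(valid), batch_size):
            chunk = valid[s : s + batch_size]
            probs = self.forward([a for _, a, _ in chunk], [p for _, _, p in chunk])
            for (i, a, p), v in zip(chunk, probs.data):
                out[i] = {"allele": str(a), "peptide": p, "score": float(v),
                          "error": None}
        return out

    # -- parameters and checkpointing -----------------------------------------
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = self.vocab.params()
        if self.encoder is not None:
            ps += self.encoder.params()
        if self.normalizer is not None:
            ps += self.normalizer.params()
        ps += self.net.params()
        return ps

    def save(self, path: str):
        """Binary weights (.npz) plus a plain-text JSON metadata sidecar."""
        import json
        import hashlib

        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        if isinstance(self.normalizer, object) and hasattr(
            self.normalizer, "running_mean"
        ):
            arrays["running_mean"] = self.normalizer.running_mean
            arrays["running_var"] = self.normalizer.running_var
        np.savez(path, **arrays)
        vocab_hash = hashlib.sha256("".join(self.vocab.symbols).encode()).hexdigest()
        meta = {
            "config": self.config.to_dict(),
            "vocab_sha256": vocab_hash,
            "n_params": len(self.params()),
        }
        if self.config.encoding == "one-hot":
            meta["alleles"] = sorted(self.encoder.index)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "PairScorer":
        import json

        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        cfg_d = dict(meta["config"])
        cfg_d["blockconv"] = BlockConvConfig(**cfg_d["blockconv"])
        config = ScorerConfig(**cfg_d)
        alleles = None
        if config.encoding == "one-hot":
            alleles = [parse_allele(a) for a in meta["alleles"]]
        scorer = cls(config, alleles=alleles)
        npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        import os

        if not os.path.exists(npz_path):
            npz_path = str(path)
        data = np.load(npz_path)
        for i, p in enumerate(scorer.params()):
            p.data[...] = data[f"p{i}"]
        if "running_mean" in data and hasattr(scorer.normalizer, "running_mean"):
            scorer.normalizer.running_mean = data["running_mean"]
            scorer.normalizer.running_var = data["running_var"]
            scorer.normalizer._initialized = True
        return scorer
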