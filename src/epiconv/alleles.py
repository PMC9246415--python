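"""HLA class II β-chain allele parsing and hierarchical encoding.

MHC-II allele names (``GENE*field1:field2``, e.g. ``DRB1*01:02``) form a
three-level hierarchy: the locus (layer 0), the serological group
(layer 1) and the protein variant (layer 2).  Related subtypes share
nomenclature prefixes and, biologically, parts of their ligandome, so
encoding each layer with its own embedding table lets a downstream model
pool evidence across related alleles — unlike one-hot encoding, which
treats every subtype as unrelated.

Each layer token indexes a 99-row x ``dim``-column embedding table; the
three 1x``dim`` rows are stacked into a 3x``dim`` matrix and fused into a
single 1x``dim`` head vector, either by per-layer linear maps summed under
a nonlinearity ("add" mode) or by a learned collapse of the stacked
matrix over the layer axis ("concat" modes, optionally with one table
shared across layers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, embedding_lookup

__all__ = [
    "HlaAllele",
    "LayerEmbeddingTable",
    "LayerFusionParams",
    "HierarchicalEncoder",
    "OneHotEncoder",
    "parse_allele",
    "tokenize_layers",
    "BETA_CHAIN_GENES",
    "GENE_INDEX",
    "TABLE_ROWS",
    "EMBED_DIM",
]

#: β-chain loci accepted (α chains contribute little to ligand specificity)
BETA_CHAIN_GENES = ("DRB1", "DRB3", "DRB4", "DRB5", "DPB1", "DQB1")
#: fixed injective gene -> layer-0 token map
GENE_INDEX = {g: i for i, g in enumerate(BETA_CHAIN_GENES)}
ALPHA_CHAIN_GENES = ("DPA1", "DQA1", "DRA", "DRA1")

TABLE_ROWS = 99  #: rows per layer embedding table
EMBED_DIM = 128  #: default embedding width

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([A-Z]+[0-9]*)\*([0-9]+)(?::([0-9]+))?$"
)


@dataclass(frozen=True)
class HlaAllele:
    """A parsed two-field β-chain allele: the unit of hierarchical encoding."""

    gene: str
    field1: int
    field2: int
    raw_name: str = ""

    def __post_init__(self):
        if self.gene not in GENE_INDEX:
            raise ValueError(f"unsupported gene {self.gene!r}")
        for f in (self.field1, self.field2):
            if not (0 <= f < TABLE_ROWS):
                raise ValueError(
                    f"field value {f} outside embedding-table range "
                    f"[0, {TABLE_ROWS - 1}]"
                )

    def format(self, prefix: bool = False) -> str:
        s = f"{self.gene}*{self.field1:02d}:{self.field2:02d}"
        return "HLA-" + s if prefix else s

    def __str__(self) -> str:
        return self.format()


def parse_allele(name: str) -> HlaAllele:
    """Parse an allele string into its three-level node.

    Accepts an optional ``HLA-`` prefix.  Rejects α-chain loci, one-field
    names, unknown genes and field values beyond the embedding-table bound.
    """
    if not name or not name.strip():
        raise ValueError("empty allele name")
    m = _ALLELE_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable allele name {name!r}")
    gene, f1, f2 = m.group(1), m.group(2), m.group(3)
    if gene in ALPHA_CHAIN_GENES:
        raise ValueError(
            f"alpha-chain locus {gene!r} unsupported: only β-chain loci "
            f"{BETA_CHAIN_GENES} carry the ligand specificity modelled here"
        )
    if gene not in GENE_INDEX:
        raise ValueError(f"unknown MHC-II β-chain locus {gene!r}")
    if f2 is None:
        raise ValueError(
            f"one-field name {name!r}: two-field nomenclature required"
        )
    field1, field2 = int(f1), int(f2)
    if field1 >= TABLE_ROWS or field2 >= TABLE_ROWS:
        raise ValueError(
            f"field value ≥ {TABLE_ROWS} in {name!r} exceeds the "
            "embedding-table bound"
        )
    return HlaAllele(gene, field1, field2, raw_name=name.strip())


def tokenize_layers(allele: HlaAllele) -> tuple[int, int, int]:
    """Integer tokens for layers 0..2: (gene index, field1, field2)."""
    return (GENE_INDEX[allele.gene], allele.field1, allele.field2)


class LayerEmbeddingTable:
    """Per-layer (or shared) 99 x dim token embedding tables.

    mode "per-layer": three independent tables; mode "shared": one table
    reused for every layer, pooling statistical strength when subtype
    coverage is sparse.
    """

    def __init__(self, dim: int = EMBED_DIM, mode: str = "per-layer", seed: int = 0):
        if mode not in ("per-layer", "shared"):
            raise ValueError(f"unknown table mode {mode!r}")
        self.dim = dim
        self.mode = mode
        self.seed = seed
        rng = np.random.default_rng(seed)
        n_tables = 1 if mode == "shared" else 3
        self.tables = [
            Tensor(rng.standard_normal((TABLE_ROWS, dim)) * 0.1, requires_grad=True)
            for _ in range(n_tables)
        ]

    def table_for_layer(self, layer: int) -> Tensor:
        return self.tables[0] if self.mode == "shared" else self.tables[layer]

    def params(self) -> list[Tensor]:
        return list(self.tables)


def embed_layers(
    tokens: np.ndarray, tables: LayerEmbeddingTable
) -> Tensor:
    """Look up the (..., 3) token array -> (..., 3, dim) layer matrix."""
    tokens = np.asarray(tokens)
    rows = [
        embedding_lookup(tables.table_for_layer(i), tokens[..., i])
        for i in range(3)
    ]
    from .autodiff import concat

    expanded = [r.reshape(*r.shape[:-1], 1, tables.dim) for r in rows]
    return concat(expanded, axis=-2)


class LayerFusionParams:
    """Learned parameters collapsing the 3 x dim layer matrix to 1 x dim.

    fusion_mode "add": e = σ(Σ_i E_i W_i) with per-layer dim x dim transfer
    matrices.  "concat"/"shared-concat": a learned depthwise kernel over
    the layer axis collapses the stacked matrix (the table-sharing of
    "shared-concat" lives in LayerEmbeddingTable, not here).
    """

    FUSION_MODES = ("add", "concat", "shared-concat")

    def __init__(
        self,
        dim: int = EMBED_DIM,
        fusion_mode: str = "concat",
        activation: str = "relu",
        seed: int = 0,
    ):
        if fusion_mode not in self.FUSION_MODES:
            raise ValueError(f"unknown fusion mode {fusion_mode!r}")
        if activation not in ("relu", "identity", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.dim = dim
        self.fusion_mode = fusion_mode
        self.activation = activation
        rng = np.random.default_rng(seed)
        if fusion_mode == "add":
            scale = 1.0 / np.sqrt(dim)
            self.W = [
                Tensor(rng.standard_normal((dim, dim)) * scale, requires_grad=True)
                for _ in range(3)
            ]
            self.bias = Tensor(np.zeros(dim), requires_grad=True)
        else:
            # depthwise collapse kernel over the 3 layer rows
            self.kernel = Tensor(
                rng.standard_normal((3, dim)) / np.sqrt(3), requires_grad=True
            )
            self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def params(self) -> list[Tensor]:
        if self.fusion_mode == "add":
            return [*self.W, self.bias]
        return [self.kernel, self.bias]

    def _activate(self, x: Tensor) -> Tensor:
        if self.activation == "relu":
            return x.relu()
        if self.activation == "tanh":
            return x.tanh()
        return x


def fuse_layers(E: Tensor, params: LayerFusionParams) -> Tensor:
    """Collapse a (..., 3, dim) layer matrix into a (..., dim) head vector."""
    if E.shape[-2] != 3 or E.shape[-1] != params.dim:
        raise ValueError(
            f"layer matrix shape {E.shape} incompatible with fusion over "
            f"3 x {params.dim}"
        )
    if params.fusion_mode == "add":
        acc = None
        for i in range(3):
            term = E[..., i, :] @ params.W[i]
            acc = term if acc is None else acc + term
        return params._activate(acc + params.bias)
    # concat modes: depthwise kernel over the layer axis
    acc = None
    for i in range(3):
        term = E[..., i, :] * params.kernel[i]
        acc = term if acc is None else acc + term
    return params._activate(acc + params.bias)


class HierarchicalEncoder:
    """Tokens -> layer embeddings -> (normalization) -> fused 1 x dim head.

    Normalization between embedding and fusion is injected by the caller
    (see :mod:`epiconv.norm`); this class owns tables and fusion params.
    """

    kind = "hierarchical"

    def __init__(
        self,
        dim: int = EMBED_DIM,
        fusion_mode: str = "concat",
        activation: str = "relu",
        seed: int = 0,
    ):
        table_mode = "shared" if fusion_mode == "shared-concat" else "per-layer"
        self.dim = dim
        self.tables = LayerEmbeddingTable(dim=dim, mode=table_mode, seed=seed)
        self.fusion = LayerFusionParams(
            dim=dim, fusion_mode=fusion_mode, activation=activation, seed=seed + 1
        )

    def layer_matrix(self, tokens: np.ndarray) -> Tensor:
        return embed_layers(tokens, self.tables)

    def head(self, tokens: np.ndarray, normalizer=None) -> Tensor:
        E = self.layer_matrix(tokens)
        if normalizer is not None:
            E = normalizer(E)
        return fuse_layers(E, self.fusion)

    def params(self) -> list[Tensor]:
        return self.tables.params() + self.fusion.params()


class OneHotEncoder:
    """Ablation baseline: each distinct allele is an orthogonal indicator
    projected to ``dim`` — equivalently a flat per-allele embedding with no
    hierarchy sharing."""

    kind = "one-hot"

    def __init__(self, alleles: list[HlaAllele], dim: int = EMBED_DIM, seed: int = 0):
        keys = sorted({str(a) for a in alleles})
        self.index = {k: i for i, k in enumerate(keys)}
        self.dim = dim
        rng = np.random.default_rng(seed)
        self.projection = Tensor(
            rng.standard_normal((len(keys), dim)) * 0.1, requires_grad=True
        )

    def indicator(self, allele: HlaAllele) -> np.ndarray:
        v = np.zeros(len(self.index))
        v[self.index[str(allele)]] = 1.0
        return v

    def head(self, alleles: list[HlaAllele], normalizer=None) -> Tensor:
        idx = np.array([self.index[str(a)] for a in alleles])
        return embedding_lookup(self.projection, idx)

    def params(self) -> list[Tensor]:
        return [self.projection]
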