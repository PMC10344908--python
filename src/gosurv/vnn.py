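"""The ontology-structured ("visible") neural network.

Architecture
------------
The expression encoder mirrors the pruned ontology DAG. Genes are leaf
inputs (one standardized expression value each). Each term is a small block:
the blocks of its children — k-vectors for child terms, scalars for directly
annotated genes — are each scaled by a softmax attention weight, concatenated
in the DAG's deterministic child order, and passed through a linear layer,
batch normalization, and a tanh nonlinearity, yielding the term's k-neuron
state (k = 6 by default). A separate rectified scalar projection per term
("single-neuron activation") summarizes the term's state for reporting. The
root's k-vector is the expression embedding.

Attention is additive: for parent p and child block h_c,
``score_c = v_p . tanh(W_p h_c + b_p)`` with a separate scorer matrix for
k-dimensional term children and scalar gene children; the softmax over all
of p's children makes the weights nonnegative and sum to one, which is what
lets fixed depth-banded cutoffs flag discriminating terms.

The drug encoder is a plain multilayer perceptron over the fingerprint bits
(2048 -> 64 -> 32 -> 4 by default; rectifier hidden layers, tanh output).
The head concatenates the expression embedding and drug embedding
(6 + 4 = 10) into a two-layer perceptron; stage 1 ends in a sigmoid
(probability of long-lived), stage 2 is linear (log months-to-death).

All weights live in a flat name -> Tensor dict so the two-stage transfer is
an exact, inspectable copy of encoder and drug-encoder entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._autograd import (Adam, Tensor, concat,  # noqa: F401
                        repeat_cols, softmax)
from .ontology import OntologyDAG

__all__ = ["VNNConfig", "ModelState", "AttentionReport", "build_model",
           "forward_encoder", "forward_drug", "forward_head",
           "forward_batch", "parameter_count", "save_model", "load_model"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class VNNConfig:
    k_term_neurons: int = 6
    drug_layer_sizes: tuple[int, ...] = (64, 32, 4)
    n_bits: int = 2048
    head_hidden: int = 16
    attention: str = "softmax_additive"
    seed: int = 0

    def __post_init__(self):
        if self.k_term_neurons <= 0 or self.head_hidden <= 0 \
                or self.n_bits <= 0 or not self.drug_layer_sizes:
            raise ValueError("all architecture sizes must be positive")
        if self.attention != "softmax_additive":
            raise ValueError(f"unknown attention form {self.attention!r}")

    @property
    def drug_embedding_dim(self) -> int:
        return self.drug_layer_sizes[-1]


@dataclass
class ModelState:
    """All weights of encoder + drug encoder + active head."""

    dag: OntologyDAG
    config: VNNConfig
    params: dict[str, Tensor]
    stage: str = "stage1"               # {"stage1", "stage2"}
    metadata: dict = dc_field(default_factory=dict)

    def trainable(self) -> list[Tensor]:
        return [t for t in self.params.values() if t.requires_grad]

    def dag_hash(self) -> str:
        import hashlib
        payload = json.dumps({
            "topo": self.dag.topo_order,
            "edges": {t: self.dag.child_edges.get(t, [])
                      for t in sorted(self.dag.terms)},
            "genes": {t: g for t, g in
                      sorted(self.dag.gene_annotations.items())},
            "k": self.config.k_term_neurons,
            "drug": list(self.config.drug_layer_sizes),
            "n_bits": self.config.n_bits,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def encoder_param_names(self) -> list[str]:
        """Encoder + drug-encoder weights: everything the transfer copies."""
        return [k for k in self.params
                if k.startswith(("term/", "att/", "drug/"))]


@dataclass
class AttentionReport:
    """Per-patient interpretability output of one encoder forward pass.

    `weights[t]` is the softmax attention weight the term received in its
    parent's context (for a multi-parent term, the maximum over parents);
    `activations[t]` is the term's rectified scalar activation. Flags are
    filled in by the depth-banded cutoff rule.
    """

    patient_id: str
    weights: dict[str, float]
    depths: dict[str, int]
    activations: dict[str, float]
    flags: dict[str, bool] = dc_field(default_factory=dict)
    parent_weights: dict[str, dict[str, float]] = dc_field(
        default_factory=dict)  # parent -> child (term or gene) -> weight


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _term_children(dag: OntologyDAG, term: str) -> tuple[list[str], list[str]]:
    """(child terms, annotated genes), each in the DAG's deterministic order;
    terms precede genes in the concatenation."""
    return (dag.child_edges.get(term, []),
            dag.gene_annotations.get(term, []))


def build_model(dag: OntologyDAG, config: VNNConfig,
                stage: str = "stage1") -> ModelState:
    """Compile the pruned DAG into an initialized model.

    Weight shapes are a pure function of (dag, config); initialization is
    deterministic in ``config.seed``.
    """
    dag.validate()
    k = config.k_term_neurons
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}

    def p(name: str, arr: np.ndarray, trainable: bool = True) -> None:
        params[name] = Tensor(arr, requires_grad=trainable)

    for t in dag.topo_order:
        kids, genes = _term_children(dag, t)
        in_dim = len(kids) * k + len(genes)
        if in_dim == 0:
            raise ValueError(f"term {t!r} has no children and no genes")
        p(f"term/{t}/W", _glorot(rng, in_dim, k, (in_dim, k)))
        p(f"term/{t}/b", np.zeros(k))
        p(f"term/{t}/bn_gamma", np.ones(k))
        p(f"term/{t}/bn_beta", np.zeros(k))
        p(f"term/{t}/bn_mean", np.zeros(k), trainable=False)
        p(f"term/{t}/bn_var", np.ones(k), trainable=False)
        p(f"term/{t}/q", _glorot(rng, k, 1, (k, 1)))
        p(f"term/{t}/q_b", np.zeros(1))
        # additive attention scorer over this parent's children
        if kids:
            p(f"att/{t}/Wt", _glorot(rng, k, k, (k, k)))
        if genes:
            p(f"att/{t}/Wg", _glorot(rng, 1, k, (1, k)))
        p(f"att/{t}/b", np.zeros(k))
        p(f"att/{t}/v", _glorot(rng, k, 1, (k, 1)))

    sizes = (config.n_bits,) + tuple(config.drug_layer_sizes)
    for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
        p(f"drug/{i}/W", _glorot(rng, fi, fo, (fi, fo)))
        p(f"drug/{i}/b", np.zeros(fo))

    head_in = k + config.drug_embedding_dim
    p("head/0/W", _glorot(rng, head_in, config.head_hidden,
                          (head_in, config.head_hidden)))
    p("head/0/b", np.zeros(config.head_hidden))
    p("head/1/W", _glorot(rng, config.head_hidden, 1,
                          (config.head_hidden, 1)))
    p("head/1/b", np.zeros(1))

    return ModelState(dag=dag, config=config, params=params, stage=stage,
                      metadata={"seed": config.seed})


def parameter_count(dag: OntologyDAG, config: VNNConfig) -> int:
    """Trainable parameter count, computed from the DAG's degree sequence."""
    k = config.k_term_neurons
    n = 0
    for t in dag.topo_order:
        kids, genes = _term_children(dag, t)
        in_dim = len(kids) * k + len(genes)
        n += in_dim * k + k          # linear
        n += 2 * k                   # bn gamma/beta
        n += k + 1                   # scalar projection
        n += (k * k if kids else 0) + (k if genes else 0)  # att W
        n += k + k                   # att b, v
    sizes = (config.n_bits,) + tuple(config.drug_layer_sizes)
    n += sum(fi * fo + fo for fi, fo in zip(sizes[:-1], sizes[1:]))
    head_in = k + config.drug_embedding_dim
    n += head_in * config.head_hidden + config.head_hidden
    n += config.head_hidden + 1
    return n


def _batchnorm(model: ModelState, term: str, x: Tensor,
               train_mode: bool) -> Tensor:
    P = model.params
    gamma, beta = P[f"term/{term}/bn_gamma"], P[f"term/{term}/bn_beta"]
    rm, rv = P[f"term/{term}/bn_mean"], P[f"term/{term}/bn_var"]
    if train_mode:
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=0, keepdims=True)
        # update running statistics (population estimates, momentum 0.1)
        rm.data = (1 - _BN_MOMENTUM) * rm.data \
            + _BN_MOMENTUM * mu.data.ravel()
        rv.data = (1 - _BN_MOMENTUM) * rv.data \
            + _BN_MOMENTUM * var.data.ravel()
        xhat = centered * ((var + _BN_EPS) ** -0.5)
    else:
        xhat = (x - Tensor(rm.data)) * Tensor((rv.data + _BN_EPS) ** -0.5)
    return xhat * gamma + beta


def _encode(model: ModelState, X: Tensor, train_mode: bool,
            attention_override: dict[str, np.ndarray] | None = None,
            compute_scalars: bool = True,
            ) -> tuple[Tensor, dict[str, Tensor],
                       dict[str, np.ndarray], dict[str, Tensor]]:
    """Run the DAG encoder on a batch.

    Returns (root state, per-term states, per-parent attention weight
    arrays, per-term scalar activations). `attention_override` replaces the
    computed softmax weights of the named parents with fixed per-child
    weights — an analysis hook for influence probes, not used in training.
    Scalar activations feed reporting only; the training path skips them.
    """
    dag, P = model.dag, model.params
    states: dict[str, Tensor] = {}
    att_out: dict[str, np.ndarray] = {}
    scalars: dict[str, Tensor] = {}
    gene_col = {g: i for i, g in enumerate(dag.genes())}
    B = X.data.shape[0]
    k = model.config.k_term_neurons

    for t in dag.topo_order:
        kids, genes = _term_children(dag, t)
        n_children = len(kids) + len(genes)
        term_block = concat([states[c] for c in kids], axis=1) if kids \
            else None
        gene_block = Tensor(X.data[:, [gene_col[g] for g in genes]]) \
            if genes else None
        if attention_override is not None and t in attention_override:
            w = np.asarray(attention_override[t], dtype=float)
            weights = Tensor(np.broadcast_to(w, (B, n_children)).copy())
            att_out[t] = w.copy()
        else:
            # score all term children with one matmul via reshape, and
            # likewise all gene children (blocks ordered: terms, genes)
            b_att, v = P[f"att/{t}/b"], P[f"att/{t}/v"]
            parts = []
            if kids:
                flat = term_block.reshape((B * len(kids), k))
                parts.append((((flat @ P[f"att/{t}/Wt"] + b_att).tanh()
                               @ v).reshape((B, len(kids)))))
            if genes:
                flat = gene_block.reshape((B * len(genes), 1))
                parts.append((((flat @ P[f"att/{t}/Wg"] + b_att).tanh()
                               @ v).reshape((B, len(genes)))))
            scores = parts[0] if len(parts) == 1 else concat(parts, axis=1)
            weights = softmax(scores, axis=1)
            att_out[t] = weights.data.mean(axis=0)
        blocks = concat([b for b in (term_block, gene_block)
                         if b is not None], axis=1) \
            if (term_block is not None and gene_block is not None) \
            else (term_block if term_block is not None else gene_block)
        w_exp = repeat_cols(weights, [k] * len(kids) + [1] * len(genes))
        x = (blocks * w_exp) @ P[f"term/{t}/W"] + P[f"term/{t}/b"]
        h = _batchnorm(model, t, x, train_mode).tanh()
        states[t] = h
        if compute_scalars:
            scalars[t] = (h @ P[f"term/{t}/q"] + P[f"term/{t}/q_b"]).relu()
    return states[dag.root], states, att_out, scalars


def forward_encoder(model: ModelState, expression: np.ndarray,
                    patient_id: str = "",
                    attention_override: dict[str, np.ndarray] | None = None,
                    ) -> tuple[np.ndarray, AttentionReport]:
    """Encode one standardized expression vector (inference mode).

    Returns the root k-vector embedding and an :class:`AttentionReport`
    holding, per term, the attention weight it received from its parent(s)
    (max over parents for multi-parent terms) and its scalar activation.
    """
    expression = np.asarray(expression, dtype=np.float64)
    n_genes = len(model.dag.genes())
    if expression.shape != (n_genes,):
        raise ValueError(f"expression length {expression.shape} does not "
                         f"match the {n_genes} annotated genes")
    X = Tensor(expression[None, :])
    root, _states, att, scalars = _encode(model, X, train_mode=False,
                                          attention_override=attention_override)
    weights: dict[str, float] = {model.dag.root: 1.0}
    parent_weights: dict[str, dict[str, float]] = {}
    for parent, w in att.items():
        kids, genes = _term_children(model.dag, parent)
        names = kids + genes
        parent_weights[parent] = dict(zip(names, w.tolist()))
        for c, wc in zip(kids, w[:len(kids)]):
            weights[c] = max(weights.get(c, 0.0), float(wc))
    report = AttentionReport(
        patient_id=patient_id,
        weights=weights,
        depths={t: model.dag.depth[t] for t in weights},
        activations={t: float(s.data[0, 0]) for t, s in scalars.items()},
        parent_weights=parent_weights,
    )
    return root.data[0], report


def forward_drug(model: ModelState, fingerprint: np.ndarray) -> np.ndarray:
    """Embed one fingerprint bit vector (inference mode)."""
    fp = np.asarray(fingerprint, dtype=np.float64)
    if fp.shape != (model.config.n_bits,):
        raise ValueError(f"fingerprint length {fp.shape} != n_bits "
                         f"{model.config.n_bits}")
    return _drug_forward(model, Tensor(fp[None, :])).data[0]


def _drug_forward(model: ModelState, FP: Tensor) -> Tensor:
    h = FP
    n_layers = len(model.config.drug_layer_sizes)
    for i in range(n_layers):
        h = h @ model.params[f"drug/{i}/W"] + model.params[f"drug/{i}/b"]
        h = h.tanh() if i == n_layers - 1 else h.relu()
    return h


def _head_forward(model: ModelState, emb: Tensor, demb: Tensor) -> Tensor:
    h = concat([emb, demb], axis=1)
    h = (h @ model.params["head/0/W"] + model.params["head/0/b"]).relu()
    out = h @ model.params["head/1/W"] + model.params["head/1/b"]
    if model.stage == "stage1":
        out = out.sigmoid()
    return out


def forward_head(model: ModelState, embedding: np.ndarray,
                 drug_embedding: np.ndarray) -> float:
    """Combine the two embeddings into the active head's prediction.

    Stage 1: probability of long-lived in (0,1). Stage 2: log months.
    """
    k = model.config.k_term_neurons
    d = model.config.drug_embedding_dim
    emb = np.asarray(embedding, float)
    demb = np.asarray(drug_embedding, float)
    if emb.shape != (k,) or demb.shape != (d,):
        raise ValueError("embedding dimensions do not match the model "
                         f"(expected {k} and {d})")
    return float(_head_forward(model, Tensor(emb[None, :]),
                               Tensor(demb[None, :])).data[0, 0])


def forward_batch(model: ModelState, X: np.ndarray, FP: np.ndarray,
                  train_mode: bool = False) -> Tensor:
    """Full forward pass on a batch; the training path."""
    Xt = Tensor(np.asarray(X, np.float64))
    root, _, _, _ = _encode(model, Xt, train_mode=train_mode,
                            compute_scalars=False)
    demb = _drug_forward(model, Tensor(np.asarray(FP, np.float64)))
    return _head_forward(model, root, demb)


def predict(model: ModelState, X: np.ndarray, FP: np.ndarray) -> np.ndarray:
    """Inference-mode predictions for a batch; returns a 1-D array."""
    return forward_batch(model, X, FP, train_mode=False).data.ravel()


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: ModelState, path: str) -> None:
    """Serialize weights + config + DAG hash to an .npz checkpoint."""
    arrays = {k: v.data for k, v in model.params.items()}
    meta = json.dumps({
        "stage": model.stage,
        "dag_hash": model.dag_hash(),
        "config": {"k_term_neurons": model.config.k_term_neurons,
                   "drug_layer_sizes": list(model.config.drug_layer_sizes),
                   "n_bits": model.config.n_bits,
                   "head_hidden": model.config.head_hidden,
                   "attention": model.config.attention,
                   "seed": model.config.seed},
        "metadata": model.metadata,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str, dag: OntologyDAG) -> ModelState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = VNNConfig(**{**meta["config"],
                           "drug_layer_sizes":
                           tuple(meta["config"]["drug_layer_sizes"])})
        model = build_model(dag, cfg, stage=meta["stage"])
        if model.dag_hash() != meta["dag_hash"]:
            raise ValueError("checkpoint DAG hash does not match the "
                             "provided ontology")
        for k in model.params:
            model.params[k].data = z[k].copy()
        model.metadata = meta["metadata"]
    return model
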