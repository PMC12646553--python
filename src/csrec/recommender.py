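"""The assembled recommender: collaboration → temporal selection → prediction.

For a patient's t-th visit the model consumes the current diagnoses and
procedures, the medication history from visits 1..t−1, the λ-combined
co-occurrence/DDI medication graph, and emits a probability per medication
in the vocabulary.  Training is multilabel binary cross-entropy over every
visit of every patient (one patient per optimisation step, visit losses
summed), optimised with Adam plus L2 regularisation and early stopping on
validation Jaccard.  Ablation variants reroute the shared forward path:

=========  ===============================================================
variant    meaning
=========  ===============================================================
full       complete model
WO_S       temporal selection replaced by the last visit's pooled vector
WO_C       graph attention bypassed (raw pooled embeddings)
GAT_GCN    attention replaced by degree-normalised graph convolution
WO_DM      medication–diagnosis graph removed
WO_PM      medication–procedure graph removed
WO_DP      diagnosis–procedure graph removed
WO_MM      medication co-occurrence and DDI graphs removed
=========  ===============================================================
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .cohort_io import Cohort, MultiHotTriple, Vocabulary, encode_patient
from .collab_gat import CollabModule, EntityLevelSets, GatConfig, propagate
from .graph_builder import SymmetricAdjacency, build_cooccurrence_from_multihot
from .nn import Adam, Linear, Module
from .temporal_select import TemporalModule

logger = logging.getLogger(__name__)

VARIANTS = ("full", "WO_S", "WO_C", "GAT_GCN", "WO_DM", "WO_PM", "WO_DP", "WO_MM")
_GRAPH_DROPS = {"WO_DM": "md", "WO_PM": "mp", "WO_DP": "dp", "WO_MM": "mm"}


@dataclass
class ModelConfig:
    embed_dim: int = 64
    heads: int = 3
    lam: float = 1.0
    threshold: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    variant: str = "full"
    activation: str = "elu"
    negative_slope: float = 0.2
    backward_nonlinearity: str = "tanhshrink"  # or "tanh"
    include_self: bool = False
    use_edge_weight_prior: bool = False
    cooccurrence_scope: str = "patient"  # or "cohort"
    bce_reduction: str = "sum"           # or "mean"
    share_temporal_weights: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0,1)")
        if self.heads < 1:
            raise ValueError("need at least one attention head")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.cooccurrence_scope not in ("patient", "cohort"):
            raise ValueError("cooccurrence_scope must be patient or cohort")


@dataclass
class PredictionOutput:
    probs: np.ndarray
    logits: np.ndarray
    recommended: set[int]


@dataclass
class TrainReport:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopping_reason: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def bce_loss(probs: Tensor, targets: np.ndarray, reduction: str = "sum",
             eps: float = 1e-7) -> Tensor:
    """Multilabel binary cross-entropy, summed over visits and medications.

    Probabilities are clipped to [eps, 1−eps] before the logs."""
    y = np.asarray(targets, dtype=np.float64)
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {y.shape}")
    p = probs.clip(eps, 1.0 - eps)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    loss = -ll.sum()
    if reduction == "mean":
        loss = loss * (1.0 / y.size)
    return loss


def recommend(probs: np.ndarray, threshold: float) -> set[int]:
    """Medication indices with probability strictly above the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    return {int(i) for i in np.flatnonzero(np.asarray(probs) > threshold)}


class CSRecModel(Module):
    """End-to-end recommender over an encoded visit sequence."""

    def __init__(self, vocab: Vocabulary, ddi: SymmetricAdjacency | None,
                 config: ModelConfig):
        super().__init__()
        self.config = config
        self.vocab = vocab
        self.n_med = vocab.n_med
        self.ddi = (ddi.weights if ddi is not None
                    else np.zeros((self.n_med, self.n_med)))
        rng = np.random.default_rng(config.seed)
        gat_cfg = GatConfig(embed_dim=config.embed_dim, heads=config.heads,
                            negative_slope=config.negative_slope,
                            activation=config.activation,
                            include_self=config.include_self,
                            use_edge_weight_prior=config.use_edge_weight_prior)
        self.gat_cfg = gat_cfg
        self.collab = self.add_module(
            "collab", CollabModule(rng, vocab.n_diag, vocab.n_proc, vocab.n_med,
                                   gat_cfg, use_gcn=(config.variant == "GAT_GCN")))
        self.temporal = self.add_module(
            "temporal", TemporalModule(rng, gat_cfg.out_dim,
                                       config.backward_nonlinearity,
                                       config.share_temporal_weights))
        self.out = self.add_module(
            "out", Linear(rng, 3 * gat_cfg.out_dim, self.n_med))
        self._cohort_amm: np.ndarray | None = None

    # -- graph plumbing -------------------------------------------------------
    def set_cohort_cooccurrence(self, cohort: Cohort) -> None:
        """Precompute a cohort-global A_mm (used when scope='cohort')."""
        vecs = []
        for _, visits in cohort.patients:
            for enc in encode_patient(visits, self.vocab):
                vecs.append(enc.v_m)
        self._cohort_amm = build_cooccurrence_from_multihot(
            vecs, self.n_med).weights

    def _combined_weights(self, encodings: list[MultiHotTriple],
                          t: int) -> np.ndarray:
        if self.config.cooccurrence_scope == "cohort":
            if self._cohort_amm is None:
                raise RuntimeError("cohort co-occurrence not set; call "
                                   "set_cohort_cooccurrence first")
            amm = self._cohort_amm
        else:
            amm = build_cooccurrence_from_multihot(
                [e.v_m for e in encodings[:t]], self.n_med).weights
        return np.clip(amm - self.config.lam * self.ddi, 0.0, None)

    # -- forward --------------------------------------------------------------
    @staticmethod
    def _visit_actives(encodings: list[MultiHotTriple], t: int):
        out = []
        for j in range(t + 1):
            prev = encodings[j - 1].active("m") if j > 0 else np.array([], int)
            out.append({"d": encodings[j].active("d"),
                        "p": encodings[j].active("p"),
                        "m_prev": prev})
        return out

    def _entity_sets(self, encodings: list[MultiHotTriple], t: int,
                     stage2_cache: list | None = None) -> EntityLevelSets:
        """Entity-level node sets for predicting visit index t (0-based),
        i.e. from visits 0..t with medication history 0..t−1."""
        visit_actives = self._visit_actives(encodings, t)
        if self.config.variant == "WO_C":
            V_D = [self.collab.E_d[va["d"]] for va in visit_actives]
            V_P = [self.collab.E_p[va["p"]] if len(va["p"]) else None
                   for va in visit_actives]
            V_M = [self.collab.E_m[va["m_prev"]] if len(va["m_prev"]) else None
                   for va in visit_actives[1:]]
            return EntityLevelSets(V_D=V_D, V_P=V_P, V_M=V_M)
        drop = frozenset({_GRAPH_DROPS[self.config.variant]}
                         if self.config.variant in _GRAPH_DROPS else ())
        combined = self._combined_weights(encodings, t)
        return propagate(self.collab, visit_actives, combined, drop,
                         stage2_cache=stage2_cache)

    def _stage2_cache(self, encodings: list[MultiHotTriple]) -> list | None:
        """Per-visit stage-2 (diagnosis/procedure) node pairs; these do not
        depend on the prediction step, so they are shared across steps."""
        if self.config.variant in ("WO_C", "WO_DP"):
            return None
        cache = []
        for enc in encodings:
            d_idx, p_idx = enc.active("d"), enc.active("p")
            if len(p_idx) == 0:
                cache.append((self.collab.E_d[d_idx], None))
            else:
                cache.append(self.collab.diag_proc_nodes(d_idx, p_idx))
        return cache

    def forward_tensor(self, encodings: list[MultiHotTriple], t: int,
                       stage2_cache: list | None = None) -> Tensor:
        """Probability Tensor over the medication vocabulary for visit t."""
        sets = self._entity_sets(encodings, t, stage2_cache)
        rep = self.temporal.build_patient_rep(
            sets, last_only=(self.config.variant == "WO_S"))
        patient = concat([rep.d_t, rep.p_t, rep.m_prev])
        return self.out(patient).sigmoid()

    def patient_probs(self, encodings: list[MultiHotTriple]) -> list[Tensor]:
        """Per-visit probability tensors, sharing the stage-2 cache."""
        cache = self._stage2_cache(encodings)
        return [self.forward_tensor(encodings, t, cache)
                for t in range(len(encodings))]

    def forward(self, encodings: list[MultiHotTriple], t: int) -> PredictionOutput:
        with no_grad():
            probs_t = self.forward_tensor(encodings, t)
        probs = probs_t.data
        logits = np.log(probs / (1.0 - probs))
        return PredictionOutput(probs=probs, logits=logits,
                                recommended=recommend(probs,
                                                      self.config.threshold))

    # -- loss over one patient ------------------------------------------------
    def patient_loss(self, encodings: list[MultiHotTriple]) -> Tensor:
        """Summed BCE over every visit of one patient."""
        from .autodiff import stack
        probs = stack(self.patient_probs(encodings))
        targets = np.stack([e.v_m for e in encodings]).astype(np.float64)
        return bce_loss(probs, targets, self.config.bce_reduction)


def predict_cohort(model: CSRecModel, cohort: Cohort
                   ) -> list[tuple[set[int], set[int], np.ndarray]]:
    """Per-visit (true set, recommended set, score vector) across a cohort."""
    out = []
    thr = model.config.threshold
    for _, visits in cohort.patients:
        encs = encode_patient(visits, model.vocab)
        with no_grad():
            probs_list = model.patient_probs(encs)
        for t, probs_t in enumerate(probs_list):
            probs = probs_t.data
            truth = {int(i) for i in np.flatnonzero(encs[t].v_m)}
            out.append((truth, recommend(probs, thr), probs))
    return out


def train(model: CSRecModel, train_cohort: Cohort, val_cohort: Cohort | None,
          config: ModelConfig | None = None, progress: bool = False,
          stop_at_metric: float | None = None) -> TrainReport:
    """Adam training with early stopping on validation Jaccard.

    Restores the best-epoch parameters before returning.  Deterministic for
    a fixed config seed (single-threaded NumPy).  ``stop_at_metric`` stops
    as soon as the monitored Jaccard reaches the given value (useful for
    capacity/overfitting probes)."""
    from .eval_metrics import EvalBatch, jaccard

    config = config or model.config
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    encoded = [encode_patient(visits, model.vocab)
               for _, visits in train_cohort.patients]
    report = TrainReport()
    best_metric, best_state, best_epoch = -np.inf, None, -1
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(encoded))
        total = 0.0
        for pi in order:
            opt.zero_grad()
            loss = model.patient_loss(encoded[pi])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += loss.item()
        entry = {"epoch": epoch, "train_loss": total}
        eval_cohort = val_cohort if val_cohort is not None else train_cohort
        preds = predict_cohort(model, eval_cohort)
        batch = EvalBatch(pairs=[(y, yh, s) for y, yh, s in preds],
                          ddi=None)
        entry["val_jaccard"] = jaccard(batch)
        report.epochs.append(entry)
        if progress:
            logger.info("epoch %d loss %.4f val_jaccard %.4f",
                        epoch, total, entry["val_jaccard"])
        improved = entry["val_jaccard"] > best_metric
        if improved:
            best_metric = entry["val_jaccard"]
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        if stop_at_metric is not None and best_metric >= stop_at_metric:
            report.stopping_reason = f"target metric {stop_at_metric} reached"
            break
        if not improved:
            since_best += 1
            if since_best >= config.patience:
                report.stopping_reason = (
                    f"no validation improvement for {config.patience} epochs")
                break
    else:
        report.stopping_reason = "max_epochs reached"
    if best_state is not None:
        model.load_state_dict(best_state)
    report.best_epoch = best_epoch
    return report


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: CSRecModel, path: str | Path) -> None:
    """Single-archive checkpoint: canonical-JSON config, parameter blobs,
    vocabulary (full maps, plus a content hash for quick mismatch checks)."""
    import hashlib
    path = Path(path)
    vocab_json = json.dumps({"diag": model.vocab.diag_index,
                             "proc": model.vocab.proc_index,
                             "med": model.vocab.med_index}, sort_keys=True)
    meta = {"config": asdict(model.config),
            "vocab_hash": hashlib.sha256(vocab_json.encode()).hexdigest()}
    import io
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, sort_keys=True, indent=1))
        zf.writestr("vocab.json", vocab_json)
        buf = io.BytesIO()
        np.savez(buf, ddi=model.ddi,
                 **{f"param/{k}": v for k, v in model.state_dict().items()})
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> CSRecModel:
    import io
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("config.json"))
        vocab_raw = json.loads(zf.read("vocab.json"))
        blobs = np.load(io.BytesIO(zf.read("params.npz")))
    vocab = Vocabulary(diag_index=vocab_raw["diag"],
                       proc_index=vocab_raw["proc"],
                       med_index=vocab_raw["med"])
    config = ModelConfig(**meta["config"])
    model = CSRecModel(vocab, SymmetricAdjacency(weights=blobs["ddi"]), config)
    model.load_state_dict({k[len("param/"):]: blobs[k]
                           for k in blobs.files if k.startswith("param/")})
    return model
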