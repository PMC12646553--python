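"""Neighbor-focused multi-head graph attention over the medical-entity graphs.

The attention layer departs from the standard formulation in one respect:
a node's own feature is excluded from its neighborhood, so the update for
node i aggregates neighbor information only.  This sharpens cross-entity
synergy signals (a diagnosis node is rebuilt purely from the procedures and
medications it co-occurs with) at the cost of discarding the node's prior
content, which the surrounding modules reinject through the embedding
tables.  A flag restores the conventional self-inclusive neighborhood for
comparison, and a GCN aggregation path backs the ablation variant that
swaps attention for symmetric-degree-normalised convolution.

Propagation runs in three ordered stages per prediction step:

1. medication nodes over the λ-combined co-occurrence/DDI graph;
2. diagnosis and procedure nodes over the within-visit complete
   diagnosis–procedure bipartite graph;
3. cross-updates over the medication–diagnosis and medication–procedure
   bipartite graphs using the stage-1/2 outputs, yielding the entity-level
   node sets consumed by the temporal module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import Module, xavier_uniform

_ACTIVATIONS = {
    "elu": lambda t: t.elu(),
    "tanh": lambda t: t.tanh(),
    "leaky_relu": lambda t: t.leaky_relu(0.2),
    "identity": lambda t: t,
}


@dataclass
class GatConfig:
    embed_dim: int = 64
    heads: int = 3
    negative_slope: float = 0.2
    activation: str = "elu"
    include_self: bool = False       # True restores the standard GAT neighborhood
    use_edge_weight_prior: bool = False

    @property
    def head_dim(self) -> int:
        return max(1, round(self.embed_dim / self.heads))

    @property
    def out_dim(self) -> int:
        return self.heads * self.head_dim


class AttentionHead(Module):
    """One attention head: a shared linear map and a length-2·d_head score
    vector applied to concatenated (target, source) mapped features."""

    def __init__(self, rng: np.random.Generator, in_dim: int, head_dim: int):
        super().__init__()
        self.W = self.register("W", xavier_uniform(rng, in_dim, head_dim))
        self.a = self.register("a", xavier_uniform(rng, 2 * head_dim, 1,
                                                   (2 * head_dim,)))


def attention_weights(h_target: Tensor, h_sources: Tensor, attn_vector: Tensor,
                      negative_slope: float = 0.2,
                      edge_weights: np.ndarray | None = None) -> Tensor:
    """Normalised attention over the neighbor rows of ``h_sources``.

    weight_j ∝ exp(LeakyReLU(a · [h_i ∥ h_j])); optional positive edge
    weights multiply the exponentials before normalisation.
    """
    k = h_sources.shape[0]
    if k == 0:
        raise ValueError("isolated node: empty neighbor set")
    dh = h_target.shape[0]
    a_self, a_neigh = attn_vector[0:dh], attn_vector[dh:2 * dh]
    logits = (h_sources @ a_neigh) + (h_target @ a_self)
    logits = logits.leaky_relu(negative_slope)
    # subtract the max for numerical stability; constant shift cancels
    shifted = logits - float(np.max(logits.data))
    ex = shifted.exp()
    if edge_weights is not None:
        ex = ex * np.asarray(edge_weights, dtype=np.float64)
    return ex / ex.sum()


def aggregate_neighbors(h_sources: Tensor, weights: Tensor,
                        activation: str = "elu") -> Tensor:
    """activation(Σ_j weight_j · h_j) over the neighbor rows only."""
    agg = weights @ h_sources
    return _ACTIVATIONS[activation](agg)


def multi_head_aggregate(target_feat: Tensor, source_feats: Tensor | None,
                         heads: list[AttentionHead], cfg: GatConfig,
                         edge_weights: np.ndarray | None = None) -> Tensor:
    """Concatenation over heads of attention-weighted neighbor aggregates.

    An isolated node (``source_feats`` None or empty) bypasses aggregation
    and keeps its per-head linearly mapped feature, unactivated.
    """
    outs = []
    isolated = source_feats is None or source_feats.shape[0] == 0
    for head in heads:
        ht = target_feat @ head.W
        if isolated:
            outs.append(ht)
            continue
        hs = source_feats @ head.W
        w = attention_weights(ht, hs, head.a, cfg.negative_slope, edge_weights)
        outs.append(aggregate_neighbors(hs, w, cfg.activation))
    return concat(outs)


class GatLayer(Module):
    """H independent attention heads updating target nodes from source nodes."""

    def __init__(self, rng: np.random.Generator, cfg: GatConfig):
        super().__init__()
        self.cfg = cfg
        self.heads = [self.add_module(f"head{h}",
                                      AttentionHead(rng, cfg.out_dim, cfg.head_dim))
                      for h in range(cfg.heads)]

    def update(self, targets: Tensor, sources: Tensor,
               neighbor_lists: list[np.ndarray],
               edge_weight_rows: list[np.ndarray] | None = None) -> Tensor:
        """Row i of the result is the multi-head update of target i attending
        over ``sources[neighbor_lists[i]]``."""
        rows = []
        for i, nbrs in enumerate(neighbor_lists):
            src = sources[nbrs] if len(nbrs) else None
            ew = None
            if edge_weight_rows is not None and len(nbrs):
                ew = edge_weight_rows[i]
            rows.append(multi_head_aggregate(targets[i], src, self.heads,
                                             self.cfg, ew))
        return stack(rows)

    def update_complete(self, targets: Tensor, sources: Tensor) -> Tensor:
        """Fast path for complete bipartite graphs: every target attends over
        every source.  Algebraically identical to `update` with full
        neighbor lists (verified in the test suite)."""
        nt = targets.shape[0]
        outs = []
        for head in self.heads:
            Ht = targets @ head.W
            Hs = sources @ head.W
            dh = self.cfg.head_dim
            a_self, a_neigh = head.a[0:dh], head.a[dh:2 * dh]
            si = (Ht @ a_self).reshape(nt, 1)
            sj = Hs @ a_neigh
            logits = (si + sj).leaky_relu(self.cfg.negative_slope)
            ex = (logits - float(np.max(logits.data))).exp()
            attn = ex / ex.sum(axis=1, keepdims=True)
            outs.append(_ACTIVATIONS[self.cfg.activation](attn @ Hs))
        return concat(outs, axis=1)


class GcnLayer(Module):
    """Symmetric-degree-normalised graph convolution (ablation path)."""

    def __init__(self, rng: np.random.Generator, cfg: GatConfig):
        super().__init__()
        self.cfg = cfg
        self.W = self.register("W", xavier_uniform(rng, cfg.out_dim, cfg.out_dim))

    def __call__(self, features: Tensor, adjacency: np.ndarray) -> Tensor:
        return gcn_aggregate(features, adjacency, self.W, self.cfg.activation)


def gcn_aggregate(features: Tensor, adjacency: np.ndarray, weight: Tensor,
                  activation: str = "elu") -> Tensor:
    """activation(D^{-1/2} (A + I) D^{-1/2} X W) with self-loops added."""
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    D_inv_sqrt = 1.0 / np.sqrt(d)
    norm = A_hat * D_inv_sqrt[:, None] * D_inv_sqrt[None, :]
    return _ACTIVATIONS[activation]((Tensor(norm) @ features) @ weight)


@dataclass
class EntityLevelSets:
    """Per-visit entity-node matrices produced by the collaborative module.

    ``V_D``/``V_P`` have one entry per visit 1..t; ``V_M`` one per visit
    1..t−1.  Each entry is an (n_active, d) Tensor (or None when the visit
    has no active codes of that type).
    """

    V_D: list[Tensor]
    V_P: list[Tensor | None]
    V_M: list[Tensor | None] = field(default_factory=list)


class CollabModule(Module):
    """Embedding tables plus the staged GAT propagation."""

    def __init__(self, rng: np.random.Generator, n_diag: int, n_proc: int,
                 n_med: int, cfg: GatConfig, use_gcn: bool = False):
        super().__init__()
        self.cfg = cfg
        self.use_gcn = use_gcn
        d = cfg.out_dim  # effective width: heads × head_dim
        scale = 1.0 / np.sqrt(d)
        self.E_d = self.register("E_d", rng.normal(0, scale, (max(n_diag, 1), d)))
        self.E_p = self.register("E_p", rng.normal(0, scale, (max(n_proc, 1), d)))
        self.E_m = self.register("E_m", rng.normal(0, scale, (max(n_med, 1), d)))
        if use_gcn:
            self.gcn_m = self.add_module("gcn_m", GcnLayer(rng, cfg))
            self.gcn_dp = self.add_module("gcn_dp", GcnLayer(rng, cfg))
            self.gcn_md = self.add_module("gcn_md", GcnLayer(rng, cfg))
            self.gcn_mp = self.add_module("gcn_mp", GcnLayer(rng, cfg))
        else:
            self.gat_m = self.add_module("gat_m", GatLayer(rng, cfg))
            self.gat_dp = self.add_module("gat_dp", GatLayer(rng, cfg))
            self.gat_md = self.add_module("gat_md", GatLayer(rng, cfg))
            self.gat_mp = self.add_module("gat_mp", GatLayer(rng, cfg))

    # -- stage 1 --------------------------------------------------------------
    def medication_nodes(self, med_union: np.ndarray,
                         combined_weights: np.ndarray) -> Tensor | None:
        """GAT update of the active medication nodes over the combined graph.

        ``combined_weights`` is the full |M|×|M| combined matrix; the
        neighborhood of med i is its strictly positive entries within
        ``med_union``, excluding i itself unless ``include_self``.
        """
        if len(med_union) == 0:
            return None
        feats = self.E_m[med_union]
        sub = combined_weights[np.ix_(med_union, med_union)]
        if self.use_gcn:
            return self.gcn_m(feats, (sub > 0).astype(float))
        nbr_lists, ew_rows = [], []
        for local_i in range(len(med_union)):
            row = sub[local_i].copy()
            if not self.cfg.include_self:
                row[local_i] = 0.0
            nbrs = np.flatnonzero(row > 0)
            nbr_lists.append(nbrs)
            ew_rows.append(row[nbrs])
        ew = ew_rows if self.cfg.use_edge_weight_prior else None
        return self.gat_m.update(feats, feats, nbr_lists, ew)

    # -- stage 2 --------------------------------------------------------------
    def diag_proc_nodes(self, diag_idx: np.ndarray,
                        proc_idx: np.ndarray) -> tuple[Tensor, Tensor | None]:
        """Cross-update diagnosis and procedure nodes over the complete
        within-visit bipartite graph; either side empty leaves the other's
        raw embeddings in place."""
        e_d = self.E_d[diag_idx]
        e_p = self.E_p[proc_idx] if len(proc_idx) else None
        if e_p is None or len(diag_idx) == 0:
            return e_d, e_p
        if self.use_gcn:
            return self._gcn_bipartite(self.gcn_dp, e_d, e_p)
        v_d = self.gat_dp.update_complete(e_d, e_p)
        v_p = self.gat_dp.update_complete(e_p, e_d)
        return v_d, v_p

    # -- stage 3 --------------------------------------------------------------
    def cross_update(self, layer_name: str, targets: Tensor,
                     sources: Tensor | None) -> Tensor:
        """Update every target node by attending over all source nodes."""
        if sources is None or sources.shape[0] == 0:
            return targets
        if self.use_gcn:
            layer: GcnLayer = getattr(self, layer_name.replace("gat", "gcn"))
            nt = targets.shape[0]
            out_t, _ = self._gcn_bipartite(layer, targets, sources)
            return out_t
        layer = getattr(self, layer_name)
        return layer.update_complete(targets, sources)

    @staticmethod
    def _gcn_bipartite(layer: GcnLayer, left: Tensor, right: Tensor):
        nl, nr = left.shape[0], right.shape[0]
        B = np.ones((nl, nr))
        A = np.block([[np.zeros((nl, nl)), B],
                      [B.T, np.zeros((nr, nr))]])
        out = layer(concat([left, right], axis=0), A)
        return out[np.arange(nl)], out[nl + np.arange(nr)]


def propagate(collab: CollabModule, visit_actives: list[dict[str, np.ndarray]],
              combined_weights: np.ndarray,
              drop: frozenset[str] = frozenset(),
              stage2_cache: list[tuple] | None = None) -> EntityLevelSets:
    """Run the three propagation stages for one prediction step.

    ``visit_actives`` holds, per visit 1..t, the active diagnosis ('d'),
    procedure ('p') and PREVIOUS-visit medication ('m_prev') index arrays.
    ``drop`` names ablated graphs among {'mm', 'dp', 'md', 'mp'}.
    Returns per-visit node matrices; medication entries correspond to the
    medications of visit j−1 (hence length t−1 overall).

    ``stage2_cache`` may hold precomputed per-visit (v_d, v_p) stage-2
    pairs (they do not depend on the prediction step, so a caller looping
    over steps can reuse them).
    """
    med_union = np.unique(np.concatenate(
        [va["m_prev"] for va in visit_actives] + [np.array([], dtype=int)]
    )).astype(int)

    if "mm" in drop:
        med_nodes = collab.E_m[med_union] if len(med_union) else None
    else:
        med_nodes = collab.medication_nodes(med_union, combined_weights)
    local = {int(g): i for i, g in enumerate(med_union)}

    V_D, V_P, V_M = [], [], []
    for j, va in enumerate(visit_actives):
        d_idx, p_idx, m_idx = va["d"], va["p"], va["m_prev"]
        if stage2_cache is not None and j < len(stage2_cache):
            v_d, v_p = stage2_cache[j]
        elif "dp" in drop or len(p_idx) == 0:
            v_d = collab.E_d[d_idx]
            v_p = collab.E_p[p_idx] if len(p_idx) else None
        else:
            v_d, v_p = collab.diag_proc_nodes(d_idx, p_idx)
        m_rows = (med_nodes[np.array([local[int(g)] for g in m_idx])]
                  if len(m_idx) else None)

        v_d_new, v_p_new, m_new = v_d, v_p, m_rows
        if m_rows is not None:
            if "md" not in drop:
                v_d_new = collab.cross_update("gat_md", v_d, m_rows)
            if "mp" not in drop and v_p is not None:
                v_p_new = collab.cross_update("gat_mp", v_p, m_rows)
            med_updates = []
            if "md" not in drop:
                med_updates.append(collab.cross_update("gat_md", m_rows, v_d))
            if "mp" not in drop and v_p is not None:
                med_updates.append(collab.cross_update("gat_mp", m_rows, v_p))
            if med_updates:
                m_new = med_updates[0]
                for extra in med_updates[1:]:
                    m_new = (m_new + extra) * 0.5

        V_D.append(v_d_new)
        V_P.append(v_p_new)
        if j > 0:
            V_M.append(m_new)
    return EntityLevelSets(V_D=V_D, V_P=V_P, V_M=V_M)
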