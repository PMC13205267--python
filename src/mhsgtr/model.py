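"""Joint training of the multi-omics integrative clustering model.

`MHSGTR` is the model object (statsmodels-style): construct it from an
aligned :class:`~mhsgtr.io.MultiOmicsDataset` (or raw per-view arrays) plus
a :class:`TrainConfig`, call :meth:`~MHSGTR.fit`, and get an
:class:`MHSGTRResults` carrying the cluster labels, consensus graph,
attention weights, per-epoch loss trace and evaluation helpers.

The full objective, minimised by full-batch Adam over all views jointly:

    sum_v [ (1/2n)||X^v - Xrec^v||_F^2 + alpha ||W1^v||_{2,1}
            + lambda1 ||Z^v - C^v Z^v||_F^2 + lambda2 ||C^v||_F^2
            + lambda3 ||A^v - C^v||_F^2 ]
    + ||C'||_*  (tensor nuclear norm of the stacked symmetrised C^v,
                 realised by a periodic t-SVT prox plus a quadratic pull)
    + beta KL(P || S_cons)

where A^v is the per-view hybrid motif graph, S_cons is the f1-normalised
attention fusion of the symmetrised C^v, and P is the DEC-style target
distribution, held fixed between periodic refreshes. Pretraining first
minimises only the reconstruction + row-sparsity terms per view at a
smaller learning rate (1e-4 vs 1e-3 for joint training).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor, concat, softmax
from .consensus import (fuse_graphs, attention_weights, normalize_f1,
                        target_distribution_f2, kl_refinement,
                        init_attention_matrix)
from .evaluate import ClusterResult, adjusted_rand_index, clinical_enrichment, \
    logrank_test, select_k, spectral_cluster
from .io import MultiOmicsDataset
from .motifs import build_hybrid_graph
from .selfexpress import EncoderState, LossWeights
from .tensor import stack_and_rotate, tensor_nuclear_norm, tsvt_prox, unrotate

__all__ = ["TrainConfig", "TrainTrace", "MHSGTR", "MHSGTRResults"]

_TRACE_TERMS = ["reconstruction", "l21", "self_expression", "c_frobenius",
                "alignment", "tnn_pull", "kl"]


@dataclass
class TrainConfig:
    """Everything that parametrises one fit; fully determines it with `seed`."""

    weights: LossWeights = field(default_factory=LossWeights)
    eta: float = 0.5                     # first-order vs motif blend in A^v
    sigma: float | str = "auto"          # Gaussian-kernel bandwidth
    graph_mode: str = "hybrid"           # hybrid | first_order | motif
    hidden_dims: tuple[int, int] = (1024, 512)
    pretrain_lr: float = 1e-4
    train_lr: float = 1e-3
    pretrain_epochs: int = 100
    train_epochs: int = 100
    tnn_weight: float = 0.1              # tau of the t-SVT prox
    prox_every: int = 10
    target_refresh: int = 10
    leaky_slope: float = 0.01
    standardize: bool = True             # z-score features before encoding
    cluster_on: str = "s_cons"           # s_cons | cf
    n_clusters: int | None = None        # None -> eigengap selection
    k_min: int = 2
    k_max: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.pretrain_epochs < 1 or self.train_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.pretrain_lr <= 0 or self.train_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.graph_mode not in ("hybrid", "first_order", "motif"):
            raise ValueError(f"unknown graph_mode '{self.graph_mode}'")
        if self.cluster_on not in ("s_cons", "cf"):
            raise ValueError(f"unknown cluster_on '{self.cluster_on}'")


class TrainTrace:
    """Per-epoch record of every loss term and their sum."""

    def __init__(self):
        self.rows: list[dict] = []

    def log(self, phase: str, epoch: int, terms: dict[str, float],
            extras: dict[str, float] | None = None):
        total = float(sum(terms.values()))
        row = {"phase": phase, "epoch": epoch, **terms, "total": total}
        if extras:
            row.update(extras)
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


class MHSGTR:
    """Multi-omics subtype clustering model.

    Parameters
    ----------
    dataset : MultiOmicsDataset or list of ndarray
        Aligned views (same samples, same order). Raw arrays are accepted
        for graph/simulation studies.
    config : TrainConfig
    """

    def __init__(self, dataset, config: TrainConfig | None = None):
        self.config = config if config is not None else TrainConfig()
        if isinstance(dataset, MultiOmicsDataset):
            ids = dataset.views[0].sample_ids
            for v in dataset.views[1:]:
                if v.sample_ids != ids:
                    raise ValueError("views are not sample-aligned; call "
                                     "align_samples first")
            self.dataset = dataset
            self.views = [v.values for v in dataset.views]
            self.sample_ids = list(ids)
        else:
            self.dataset = None
            self.views = [np.asarray(X, dtype=np.float64) for X in dataset]
            n = self.views[0].shape[0]
            if any(X.shape[0] != n for X in self.views):
                raise ValueError("views disagree on the number of samples")
            self.sample_ids = [f"S{i:04d}" for i in range(n)]
        self.n_samples = self.views[0].shape[0]
        self.n_views = len(self.views)

    @classmethod
    def from_dataset(cls, dataset: MultiOmicsDataset,
                     config: TrainConfig | None = None) -> "MHSGTR":
        return cls(dataset, config)

    # -- graph construction ---------------------------------------------------
    def build_view_graphs(self) -> list[np.ndarray]:
        """Per-view target graphs A^v according to `graph_mode`."""
        cfg = self.config
        graphs = []
        for X in self.views:
            hg = build_hybrid_graph(X, sigma=cfg.sigma, eta=cfg.eta)
            if cfg.graph_mode == "hybrid":
                graphs.append(hg.hybrid)
            elif cfg.graph_mode == "first_order":
                graphs.append(hg.first_order)
            else:
                graphs.append(hg.motif_sim)
        return graphs

    # -- loss assembly (autodiff) ---------------------------------------------
    def _view_terms(self, Xt: Tensor, st: EncoderState, At: Tensor,
                    w: LossWeights, joint: bool) -> dict[str, Tensor]:
        n = w.n if w.n is not None else st.n_samples
        Z = st.encode(Xt)
        C = st.masked_C()
        CZ = C @ Z
        Xrec = st.decode(CZ if joint else Z)
        row_norms = ((st.W1 ** 2).sum(axis=1) + 1e-300).sqrt()
        terms = {
            "reconstruction": ((Xt - Xrec) ** 2).sum() * (1.0 / (2.0 * n)),
            "l21": row_norms.sum() * w.alpha,
        }
        if joint:
            terms["self_expression"] = ((Z - CZ) ** 2).sum() * w.lambda1
            terms["c_frobenius"] = (C ** 2).sum() * w.lambda2
            terms["alignment"] = ((At - C) ** 2).sum() * w.lambda3
        return terms

    @staticmethod
    def _sym_graph(st: EncoderState) -> Tensor:
        C = st.masked_C()
        return (C.abs() + C.abs().T) * 0.5

    def _consensus_chain(self, sym_graphs: list[Tensor], W_att: Tensor,
                         slope: float) -> tuple[Tensor, Tensor, Tensor]:
        """Differentiable attention -> fusion -> f1; returns (M_att, CF, S_cons)."""
        n = self.n_samples
        Cc = concat(sym_graphs, axis=1)
        M_att = softmax((Cc @ W_att).leaky_relu(slope), axis=1)
        CF = None
        for v, g in enumerate(sym_graphs):
            col = M_att @ Tensor(np.eye(self.n_views)[:, v:v + 1])  # N x 1
            CF = col * g if CF is None else CF + col * g
        mask = Tensor(1.0 - np.eye(n))
        off = CF * mask
        row_sums = off.sum(axis=1, keepdims=True) + 1e-12
        S = (off + off.T) / (2.0 * row_sums)
        S_cons = S * mask + Tensor(np.eye(n))
        return M_att, CF, S_cons

    @staticmethod
    def _kl_term(P: np.ndarray, S_cons: Tensor, beta: float) -> Tensor:
        Sn = S_cons / S_cons.sum(axis=1, keepdims=True)
        Pc = Tensor(P)
        mask = (P > 0).astype(float)
        logP = np.zeros_like(P)
        logP[P > 0] = np.log(P[P > 0])
        const = float((P * logP).sum())
        return (const - (Pc * (Sn + Tensor((1 - mask) * 1e-300)).log()
                         * Tensor(mask)).sum()) * beta

    # -- fitting ----------------------------------------------------------------
    def fit(self, true_labels: np.ndarray | None = None) -> "MHSGTRResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        w = cfg.weights

        views = []
        for X in self.views:
            if cfg.standardize:
                mu, sd = X.mean(axis=0), X.std(axis=0)
                sd[sd == 0] = 1.0
                views.append((X - mu) / sd)
            else:
                views.append(X.copy())
        Xts = [Tensor(X) for X in views]

        A_graphs = self.build_view_graphs()
        Ats = [Tensor(A) for A in A_graphs]

        # one shared init sub-seed across views keeps the objective exactly
        # view-exchange symmetric: identical views then evolve identically
        # and the attention stays uniform, as the symmetry argument demands
        init_seed = int(rng.integers(2 ** 31))
        states = [EncoderState(self.n_samples, X.shape[1], cfg.hidden_dims,
                               rng=np.random.default_rng(init_seed),
                               C_init=A * (1.0 - np.eye(self.n_samples)))
                  for X, A in zip(views, A_graphs)]
        trace = TrainTrace()

        # ---- pretraining: reconstruction + row sparsity only, per view ----
        for vi, (Xt, st) in enumerate(zip(Xts, states)):
            opt = Adam(st.ae_params, lr=cfg.pretrain_lr)
            for epoch in range(cfg.pretrain_epochs):
                terms = self._view_terms(Xt, st, Ats[vi], w, joint=False)
                total = terms["reconstruction"] + terms["l21"]
                if not np.isfinite(total.item()):
                    raise FloatingPointError(
                        f"pretraining diverged at view {vi}, epoch {epoch}")
                trace.log("pretrain", epoch,
                          {k: t.item() for k, t in terms.items()},
                          extras={"view": vi})
                opt.zero_grad()
                total.backward()
                opt.step()

        # ---- joint training ----
        W_att = Tensor(init_attention_matrix(self.n_samples, self.n_views),
                       requires_grad=True)
        params = [p for st in states for p in st.params] + [W_att]
        opt = Adam(params, lr=cfg.train_lr)

        P = None
        prox_targets: list[np.ndarray] | None = None

        def epoch_terms() -> tuple[dict[str, Tensor], Tensor]:
            terms: dict[str, list[Tensor]] = {}
            for Xt, st, At in zip(Xts, states, Ats):
                for k, t in self._view_terms(Xt, st, At, w, joint=True).items():
                    terms.setdefault(k, []).append(t)
            agg = {k: sum(ts[1:], ts[0]) for k, ts in terms.items()}
            syms = [self._sym_graph(st) for st in states]
            _, CF, S_cons = self._consensus_chain(syms, W_att, cfg.leaky_slope)
            if prox_targets is not None:
                pulls = [((s - Tensor(L)) ** 2).sum() * 0.5
                         for s, L in zip(syms, prox_targets)]
                agg["tnn_pull"] = sum(pulls[1:], pulls[0])
            else:
                agg["tnn_pull"] = Tensor(0.0)
            agg["kl"] = self._kl_term(P, S_cons, w.beta)
            return agg, S_cons

        def numpy_consensus() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            syms = [st.symmetrized_graph() for st in states]
            att = attention_weights(syms, W_att.data, cfg.leaky_slope)
            CF = fuse_graphs(syms, att.weights)
            return att.weights, CF, normalize_f1(CF).normalized

        for epoch in range(cfg.train_epochs + 1):
            if epoch % cfg.target_refresh == 0:
                _, _, S_now = numpy_consensus()
                P = target_distribution_f2(S_now).P
            if epoch % cfg.prox_every == 0:
                syms_np = [st.symmetrized_graph() for st in states]
                low = tsvt_prox(stack_and_rotate(syms_np), cfg.tnn_weight)
                prox_targets = unrotate(low)
            terms, _ = epoch_terms()
            vals = {k: terms[k].item() for k in _TRACE_TERMS}
            total = None
            for k in _TRACE_TERMS:
                total = terms[k] if total is None else total + terms[k]
            if not np.isfinite(total.item()):
                raise FloatingPointError(f"joint training diverged at epoch {epoch}")
            syms_now = [st.symmetrized_graph() for st in states]
            tnn_val = tensor_nuclear_norm(stack_and_rotate(syms_now))
            trace.log("train", epoch, vals, extras={"tnn": tnn_val})
            if epoch == cfg.train_epochs:
                break  # final state logged without a further step
            opt.zero_grad()
            total.backward()
            opt.step()

        M_att, CF, S_cons = numpy_consensus()
        cluster_graph = S_cons if cfg.cluster_on == "s_cons" else CF
        k = cfg.n_clusters if cfg.n_clusters is not None else \
            select_k(cluster_graph, cfg.k_min, cfg.k_max)
        cluster = spectral_cluster(cluster_graph, k,
                                   seed=int(cfg.seed % (2 ** 31)))

        return MHSGTRResults(
            model=self, config=cfg, states=states,
            view_graphs=A_graphs,
            self_expressive=[st.symmetrized_graph() for st in states],
            attention=M_att, fused=CF, consensus=S_cons,
            target=P, prox_targets=prox_targets,
            attention_matrix=W_att.data.copy(),
            cluster=cluster, trace=trace.to_frame(),
            true_labels=(np.asarray(true_labels)
                         if true_labels is not None else None))


@dataclass
class MHSGTRResults:
    """Fit artefacts: labels, graphs, attention, trace and evaluation helpers."""

    model: MHSGTR
    config: TrainConfig
    states: list[EncoderState]
    view_graphs: list[np.ndarray]       # A^v targets
    self_expressive: list[np.ndarray]   # symmetrised C^v
    attention: np.ndarray               # M_att, N x V
    fused: np.ndarray                   # CF
    consensus: np.ndarray               # S_cons
    target: np.ndarray                  # P at the last refresh
    prox_targets: list[np.ndarray] | None  # low-rank slices at the last prox
    attention_matrix: np.ndarray        # learned W_att
    cluster: ClusterResult
    trace: pd.DataFrame
    true_labels: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.cluster.labels

    @property
    def k(self) -> int:
        return self.cluster.k

    def ari(self, true_labels: np.ndarray | None = None) -> float:
        ref = true_labels if true_labels is not None else self.true_labels
        if ref is None:
            raise ValueError("no reference labels available")
        return adjusted_rand_index(ref, self.labels)

    def evaluate_survival(self, survival=None) -> dict[str, float]:
        surv = survival
        if surv is None and self.model.dataset is not None:
            surv = self.model.dataset.survival
        if surv is None:
            raise ValueError("no survival table available")
        chi2, p, nl10 = logrank_test(surv, self.labels)
        return {"chi2": chi2, "p": p, "neg_log10_p": nl10}

    def evaluate_clinical(self, clinical=None):
        clin = clinical
        if clin is None and self.model.dataset is not None:
            clin = self.model.dataset.clinical
        if clin is None:
            raise ValueError("no clinical table available")
        return clinical_enrichment(clin, self.labels)

    def final_loss_terms(self) -> dict[str, float]:
        """Last logged training-epoch loss terms (state after the final step)."""
        tr = self.trace[self.trace["phase"] == "train"]
        last = tr.iloc[-1]
        return {k: float(last[k]) for k in _TRACE_TERMS + ["total"]}

    def summary(self) -> str:
        cfg, lines = self.config, []
        lines.append("MHSGTR fit summary")
        lines.append("=" * 60)
        lines.append(f"samples: {self.model.n_samples}   views: "
                     f"{self.model.n_views}   clusters (k): {self.k}")
        sizes = np.bincount(self.labels)[1:]
        lines.append("cluster sizes: " +
                     ", ".join(f"C{i + 1}={s}" for i, s in enumerate(sizes)))
        lines.append(f"graph mode: {cfg.graph_mode} (eta={cfg.eta})   "
                     f"hidden dims: {cfg.hidden_dims}")
        mean_att = self.attention.mean(axis=0)
        lines.append("mean attention per view: " +
                     ", ".join(f"{a:.3f}" for a in mean_att))
        terms = self.final_loss_terms()
        lines.append("final loss terms:")
        for name, val in terms.items():
            lines.append(f"  {name:16s} {val:12.6f}")
        if self.true_labels is not None:
            lines.append(f"ARI vs reference labels: {self.ari():.4f}")
        surv = (self.model.dataset.survival
                if self.model.dataset is not None else None)
        if surv is not None:
            ev = self.evaluate_survival(surv)
            lines.append(f"log-rank: chi2={ev['chi2']:.3f}  p={ev['p']:.3g}  "
                         f"-log10(p)={ev['neg_log10_p']:.2f}")
        return "\n".join(lines)

    def save_checkpoint(self, path: str) -> None:
        arrays = {"attention_matrix": self.attention_matrix,
                  "consensus": self.consensus, "fused": self.fused,
                  "labels": self.labels}
        for vi, st in enumerate(self.states):
            for k, v in st.state_dict().items():
                arrays[f"view{vi}_{k}"] = v
        np.savez(path, **arrays)
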