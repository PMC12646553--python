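"""Desk-scale experiment orchestration: end-to-end runs, ablation grids,
head-count and medication-frequency sensitivity sweeps.

Every cell of a grid is fully seeded and runs the same pipeline:
simulate (or load) a cohort → medication-frequency filter → ≥2-visit
filter → patient-level split → train → score the test split with the four
metrics.  A constant top-k frequency baseline provides a sanity floor.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import Cohort, Vocabulary, build_vocabulary, filter_cohort, split_cohort
from .eval_metrics import EvalBatch, score_batch
from .graph_builder import build_ddi_matrix
from .recommender import CSRecModel, ModelConfig, VARIANTS, predict_cohort, train
from .synth_cohort import SynthConfig, ddi_pair_codes, generate

logger = logging.getLogger(__name__)


@dataclass
class FrequencyBaseline:
    """Recommends the k most frequent training medications to every visit;
    scores are occurrence frequencies normalised to [0,1]."""

    recommended: set[int]
    scores: np.ndarray

    @classmethod
    def fit(cls, train_cohort: Cohort, vocab: Vocabulary,
            k: int) -> "FrequencyBaseline":
        if k < 1:
            raise ValueError("k must be >= 1")
        counts = Counter()
        for _, visits in train_cohort.patients:
            for v in visits:
                counts.update(v.medications)
        scores = np.zeros(vocab.n_med)
        for code, n in counts.items():
            if code in vocab.med_index:
                scores[vocab.med_index[code]] = n
        top = np.lexsort((np.arange(vocab.n_med), -scores))[:k]
        total = scores.max() if scores.max() > 0 else 1.0
        return cls(recommended=set(int(i) for i in top), scores=scores / total)

    def predict_cohort(self, cohort: Cohort, vocab: Vocabulary):
        out = []
        for _, visits in cohort.patients:
            for v in visits:
                truth = {vocab.med_index[c] for c in v.medications
                         if c in vocab.med_index}
                out.append((truth, set(self.recommended), self.scores.copy()))
        return out


def frequency_baseline(train_cohort: Cohort, vocab: Vocabulary,
                       k: int) -> FrequencyBaseline:
    return FrequencyBaseline.fit(train_cohort, vocab, k)


@dataclass
class PipelineResult:
    metrics: dict[str, float]
    baseline_metrics: dict[str, float]
    report: object
    vocab: Vocabulary
    model: CSRecModel


def run_pipeline(synth_cfg: SynthConfig, model_cfg: ModelConfig,
                 min_visits: int = 2, min_med_freq: int = 0,
                 split_ratio: tuple[int, int, int] = (23, 16, 16),
                 baseline_k: int | None = None) -> PipelineResult:
    """One full simulate→filter→split→train→score run."""
    cohort, _ = generate(synth_cfg)
    cohort = filter_cohort(cohort, min_visits=min_visits,
                           min_med_freq=min_med_freq)
    vocab = build_vocabulary(cohort)
    tr, va, te = split_cohort(cohort, split_ratio, seed=model_cfg.seed)
    ddi = build_ddi_matrix(ddi_pair_codes(synth_cfg), vocab)
    model = CSRecModel(vocab, ddi, model_cfg)
    if model_cfg.cooccurrence_scope == "cohort":
        model.set_cohort_cooccurrence(tr)
    report = train(model, tr, va, model_cfg)
    preds = predict_cohort(model, te)
    metrics = score_batch(EvalBatch(pairs=preds, ddi=ddi.weights))
    if baseline_k is None:
        mean_med = np.mean([len(v.medications) for _, vs in tr.patients
                            for v in vs])
        baseline_k = max(1, int(round(mean_med)))
    base = frequency_baseline(tr, vocab, baseline_k)
    base_metrics = score_batch(EvalBatch(pairs=base.predict_cohort(te, vocab),
                                         ddi=ddi.weights))
    return PipelineResult(metrics=metrics, baseline_metrics=base_metrics,
                          report=report, vocab=vocab, model=model)


@dataclass
class ExperimentGrid:
    variants: list[str] = field(default_factory=lambda: list(VARIANTS))
    heads: list[int] = field(default_factory=list)
    med_freq_thresholds: list[int] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2])
    base_model: ModelConfig = field(default_factory=ModelConfig)
    base_synth: SynthConfig = field(default_factory=SynthConfig)
    min_med_freq: int = 0

    def __post_init__(self):
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if not self.seeds:
            raise ValueError("need at least one seed")


def _cells(grid: ExperimentGrid):
    for variant in grid.variants:
        for seed in grid.seeds:
            yield ("variant", variant,
                   replace(grid.base_model, variant=variant, seed=seed),
                   grid.min_med_freq)
    for h in grid.heads:
        for seed in grid.seeds:
            yield ("heads", h,
                   replace(grid.base_model, heads=h, seed=seed),
                   grid.min_med_freq)
    for lam in grid.lambdas:
        for seed in grid.seeds:
            yield ("lambda", lam,
                   replace(grid.base_model, lam=lam, seed=seed),
                   grid.min_med_freq)
    for thr in grid.med_freq_thresholds:
        for seed in grid.seeds:
            yield ("med_freq", thr, replace(grid.base_model, seed=seed), thr)


def run_grid(grid: ExperimentGrid, out_dir: str | Path | None = None
             ) -> pd.DataFrame:
    """Run every grid cell; individual failures are recorded and skipped.

    With ``out_dir`` set, finished cells are cached as JSON and reloaded on
    rerun, making the grid resumable."""
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for axis, setting, model_cfg, med_freq in _cells(grid):
        tag = f"{axis}-{setting}-seed{model_cfg.seed}"
        cache = out_dir / f"{tag}.json" if out_dir else None
        if cache and cache.exists():
            rows.append(json.loads(cache.read_text()))
            continue
        synth = replace(grid.base_synth, seed=grid.base_synth.seed
                        + 1000 * model_cfg.seed)
        try:
            res = run_pipeline(synth, model_cfg, min_med_freq=med_freq)
            row = {"axis": axis, "setting": str(setting),
                   "seed": model_cfg.seed, **res.metrics,
                   "baseline_jaccard": res.baseline_metrics["jaccard"]}
        except Exception as e:  # noqa: BLE001 — grid must survive cell failures
            logger.exception("grid cell %s failed", tag)
            row = {"axis": axis, "setting": str(setting),
                   "seed": model_cfg.seed, "error": str(e)}
        rows.append(row)
        if cache:
            cache.write_text(json.dumps(row))  # key order preserved for reload
    return pd.DataFrame(rows)


def aggregate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd over seeds for each (axis, setting)."""
    metrics = [c for c in ("jaccard", "prauc", "f1", "ddi", "baseline_jaccard")
               if c in table.columns]
    ok = table[~table.get("error", pd.Series(False, index=table.index)).notna()] \
        if "error" in table.columns else table
    return ok.groupby(["axis", "setting"])[metrics].agg(["mean", "std"])
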