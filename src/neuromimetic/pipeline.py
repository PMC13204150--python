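"""Leakage-free repeated stratified cross-validation and the experiment grid.

Per repeat x fold: the extractor is fitted on the training rows only and
applied to both portions; the wrapper selector runs on the transformed
training portion (its fitness uses inner folds of that portion only); the
classifier is trained on the selected columns; test accuracy (N-E)/N x 100
and the confusion counts are recorded. No test-fold information reaches any
fitted statistic.

The selector runs inside every fold by default (the strict, leakage-free
protocol); ``select_globally=True`` switches to the optimistic variant that
selects once on the full table before cross-validation, so the gap between
the two protocols can be quantified.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .classifiers import make_classifier
from .data import LabeledDataset, RunConfig, ValidationError, rng_stream
from .extraction import make_extractor
from .selection import make_selector

log = logging.getLogger(__name__)


@dataclass
class CvPlan:
    """Fold plan: stratified k-fold repeated n_repeats times."""

    n_folds: int = 10
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def validate(self) -> "CvPlan":
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        return self

    def splits(self, y: np.ndarray):
        self.validate()
        rskf = RepeatedStratifiedKFold(
            n_splits=self.n_folds, n_repeats=self.n_repeats,
            random_state=self.seed)
        yield from rskf.split(np.zeros((len(y), 1)), y)


@dataclass
class FoldResult:
    accuracy: float
    confusion: tuple[int, int, int, int]    # tn, fp, fn, tp
    n_selected: int
    selector_fitness: float


def _run_fold(dataset, config, train_idx, test_idx, rng_tag, master_seed,
              select_globally_mask=None):
    Xtr, ytr = dataset.features[train_idx], dataset.labels[train_idx]
    Xte, yte = dataset.features[test_idx], dataset.labels[test_idx]

    ext = make_extractor(config.extractor, **config.extractor_params)
    ext.fit(Xtr, ytr, rng=rng_stream(master_seed, f"{rng_tag}/extract"))
    Ztr, Zte = ext.transform(Xtr), ext.transform(Xte)

    if select_globally_mask is not None:
        mask = select_globally_mask
        sel_fitness = np.nan
    else:
        sel = make_selector(config.selector, **config.selector_params)
        res = sel.select(Ztr, ytr, rng=rng_stream(master_seed, f"{rng_tag}/select"))
        mask, sel_fitness = res.mask, res.fitness

    clf = make_classifier(config.classifier, **config.classifier_params)
    clf.fit(Ztr[:, mask], ytr, rng=rng_stream(master_seed, f"{rng_tag}/train"))
    pred = np.asarray(clf.predict(Zte[:, mask]), dtype=int)

    acc = float(np.mean(pred == yte) * 100.0)
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    tp = int(np.sum((pred == 1) & (yte == 1)))
    return FoldResult(acc, (tn, fp, fn, tp), int(mask.sum()), sel_fitness)


def cross_validate(dataset: LabeledDataset, config: RunConfig,
                   plan: CvPlan | None = None,
                   select_globally: bool = False) -> list[FoldResult]:
    """Run the configured pipeline under the fold plan; per-fold results."""
    config.validate()
    plan = plan or CvPlan(config.n_folds, config.n_repeats, seed=config.seed)
    y = dataset.labels
    if min(np.bincount(y, minlength=2)) < plan.n_folds:
        raise ValidationError(
            "minority class too small for the requested fold count")

    global_mask = None
    if select_globally:
        ext = make_extractor(config.extractor, **config.extractor_params)
        ext.fit(dataset.features, y,
                rng=rng_stream(config.seed, "global/extract"))
        Z = ext.transform(dataset.features)
        sel = make_selector(config.selector, **config.selector_params)
        global_mask = sel.select(
            Z, y, rng=rng_stream(config.seed, "global/select")).mask

    results = []
    for f, (tr, te) in enumerate(plan.splits(y)):
        t0 = time.perf_counter()
        res = _run_fold(dataset, config, tr, te, f"fold{f}", config.seed,
                        select_globally_mask=global_mask)
        log.debug("fold %d: acc=%.2f%% (%.2fs)", f, res.accuracy,
                  time.perf_counter() - t0)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def run_grid(dataset: LabeledDataset, extractors: list[str],
             selectors: list[str], classifiers: list[str],
             plan: CvPlan | None = None, seed: int = 0,
             experiment: str = "experiment", params: dict | None = None
             ) -> pd.DataFrame:
    """Cross-validate every (extractor, selector, classifier) combination.

    Returns a results table with one row per grid cell: mean accuracy (%),
    SD, and the per-fold values (JSON-encoded). ``params`` optionally maps
    component names to parameter dicts applied grid-wide.
    """
    if not (extractors and selectors and classifiers):
        raise ValidationError("extractor/selector/classifier lists must be non-empty")
    plan = plan or CvPlan(seed=seed)
    params = params or {}
    rows = []
    for ext in extractors:
        for sel in selectors:
            for clf in classifiers:
                config = RunConfig(
                    extractor=ext, extractor_params=params.get(ext, {}),
                    selector=sel, selector_params=params.get(sel, {}),
                    classifier=clf, classifier_params=params.get(clf, {}),
                    n_folds=plan.n_folds, n_repeats=plan.n_repeats, seed=seed)
                t0 = time.perf_counter()
                folds = cross_validate(dataset, config, plan)
                accs = np.array([f.accuracy for f in folds])
                log.info("grid cell (%s, %s, %s): %.2f%% +- %.2f (%.1fs)",
                         ext, sel, clf, accs.mean(), accs.std(),
                         time.perf_counter() - t0)
                rows.append({
                    "experiment": experiment,
                    "extractor": ext, "selector": sel, "classifier": clf,
                    "mean_accuracy": float(accs.mean()),
                    "sd_accuracy": float(accs.std()),
                    "fold_accuracies": json.dumps([round(a, 6) for a in accs]),
                })
    return pd.DataFrame(rows)


def report(results: pd.DataFrame, best_k: int = 5) -> pd.DataFrame:
    """Top-k grid cells by mean accuracy.

    Ties break by (selector, extractor, classifier) lexicographic order.
    """
    if results.empty:
        raise ValidationError("results table is empty")
    ordered = results.sort_values(
        by=["mean_accuracy", "selector", "extractor", "classifier"],
        ascending=[False, True, True, True], kind="stable")
    return ordered.head(best_k).reset_index(drop=True)
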