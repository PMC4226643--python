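"""Split-based success-rate protocol and hidden-neuron sweep.

The identification benchmark randomly divides the feature table into
train/test partitions at several proportions (60/40, 70/30, 80/20, 90/10),
trains one network per partition and reports the percentage of test
specimens whose predicted species equals the true species.  Splits are
stratified per species — each species keeps at least one test and one
training sample — and every reported rate is the mean over a configurable
number of seeded repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .ann import MLPModel, TrainConfig, predict_batch, train
from .features import LABEL_COLUMN

__all__ = ["EvalReport", "SweepReport", "stratified_split", "success_rate",
           "evaluate", "neuron_sweep", "write_sweep"]

DEFAULT_SPLITS = (0.6, 0.7, 0.8, 0.9)


@dataclass
class EvalReport:
    """Mean success rate (%) per train fraction, the individual repeat
    rates, pooled confusion matrices and the seeds used."""

    per_split: dict            # train_fraction -> mean rate %
    per_split_rates: dict      # train_fraction -> list of repeat rates
    confusion: dict            # train_fraction -> DataFrame (true x pred)
    seeds: dict                # train_fraction -> list of seeds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"train_fraction": list(self.per_split),
             "success_rate": [self.per_split[k] for k in self.per_split]})


@dataclass
class SweepReport:
    """Success rate (%) per hidden-layer width."""

    per_h: dict                # h -> mean rate %
    per_h_rates: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hidden": list(self.per_h),
                             "success_rate": list(self.per_h.values())})


def stratified_split(table: pd.DataFrame, train_fraction: float, seed: int):
    """Per-species random partition at ``train_fraction``.

    Rounds to the nearest count but always keeps >= 1 training and >= 1
    test sample per species; a species with a single sample is an error.
    Returns ``(train, test)`` DataFrames that partition the input rows.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for species, group in table.groupby(LABEL_COLUMN, sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(
                f"species {species!r} has a single sample; cannot split")
        k = int(round(train_fraction * n))
        k = min(max(k, 1), n - 1)
        perm = rng.permutation(n)
        idx = group.index.to_numpy()
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def success_rate(model: MLPModel, test: pd.DataFrame):
    """Percentage of correct argmax predictions on a test table, plus the
    confusion matrix (rows = true species, columns = predicted)."""
    if len(test) == 0:
        raise ValueError("empty test set")
    truth = list(test[LABEL_COLUMN])
    pred = predict_batch(model, test)
    labels = model.labels
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(truth, pred):
        conf.loc[t, p] += 1
    rate = 100.0 * sum(t == p for t, p in zip(truth, pred)) / len(truth)
    return rate, conf


def evaluate(table: pd.DataFrame, splits=DEFAULT_SPLITS, repeats: int = 3,
             config: TrainConfig = TrainConfig(), base_seed: int = 0
             ) -> EvalReport:
    """Run the full split protocol: for each train fraction, ``repeats``
    seeded train/test rounds; report mean success rates."""
    per_split, per_rates, confusions, seeds = {}, {}, {}, {}
    for frac in splits:
        rates, used = [], []
        conf_sum = None
        for r in range(repeats):
            seed = base_seed + r
            tr, te = stratified_split(table, frac, seed=seed)
            model = train(tr, replace(config, seed=seed,
                                      train_fraction=frac))
            rate, conf = success_rate(model, te)
            rates.append(rate)
            used.append(seed)
            conf_sum = conf if conf_sum is None else conf_sum + conf
        per_split[frac] = float(np.mean(rates))
        per_rates[frac] = rates
        confusions[frac] = conf_sum
        seeds[frac] = used
    return EvalReport(per_split=per_split, per_split_rates=per_rates,
                      confusion=confusions, seeds=seeds)


def neuron_sweep(table: pd.DataFrame, h_values, config: TrainConfig =
                 TrainConfig(), repeats: int = 1, base_seed: int = 0
                 ) -> SweepReport:
    """Success rate as a function of hidden-layer width.

    Trains one model per h (same split/seed policy as :func:`evaluate`);
    a training failure for one h is recorded as NaN and the sweep
    continues.
    """
    if not len(list(h_values)):
        raise ValueError("h_values must be non-empty")
    per_h, per_rates = {}, {}
    for h in h_values:
        rates = []
        for r in range(repeats):
            seed = base_seed + r
            try:
                tr, te = stratified_split(table, config.train_fraction, seed)
                model = train(tr, replace(config, hidden=int(h), seed=seed))
                rate, _ = success_rate(model, te)
            except ValueError:
                rate = float("nan")
            rates.append(rate)
        per_h[int(h)] = float(np.nanmean(rates)) if rates else float("nan")
        per_rates[int(h)] = rates
    return SweepReport(per_h=per_h, per_h_rates=per_rates)


def write_sweep(report: SweepReport, outdir, plot: bool = True) -> None:
    """Write the sweep as CSV (and a rate-vs-neurons PNG plot)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(outdir / "sweep.csv", index=False)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(list(report.per_h), list(report.per_h.values()), "o-")
        ax.set_xlabel("hidden neurons")
        ax.set_ylabel("success rate (%)")
        ax.set_ylim(0, 100)
        fig.savefig(outdir / "sweep.png", dpi=120)
        plt.close(fig)
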