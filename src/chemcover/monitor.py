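"""Training-state diagnosis from negative-log-likelihood distributions.

After each epoch the NLLs of three sets — training, validation, and a fresh
sample from the model — are collected.  Their histograms (on one shared
binning), pairwise Jensen–Shannon divergences, and mean/variance
trajectories stage the training process:

* **undertrained** — the sampled set is much more probable than held-out
  data (its mean NLL sits below the training/validation means) and the
  distributions disagree;
* **converged** — all three pairwise JSDs sit near their joint minimum: a
  held-out molecule is about as likely to be generated as a training one;
* **overtrained** — the sampled set keeps approaching the training set while
  drifting away from validation (JSD(valid, sampled) rising as
  JSD(train, sampled) falls).

The recommended epoch window intersects the converged-JSD window with the
plateau of the validation mean (nearest the uniform reference ``ln n``) and
the low-variance window (the uniform sampler has variance 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

__all__ = [
    "NllDistribution",
    "EpochDiagnostics",
    "DiagnosisReport",
    "default_bin_edges",
    "nll_distribution",
    "jensen_shannon",
    "epoch_diagnostics",
    "diagnose",
]

LN2 = float(np.log(2.0))

#: tiny mass added to every bin so KL terms stay finite under any smoothing
_SMOOTH = 1e-12


def default_bin_edges(
    mu_uniform: float, *, width: float = 0.5, extra: float = 20.0
) -> np.ndarray:
    """Shared fixed binning: width-0.5 bins on [0, mu_uniform + extra]."""
    upper = mu_uniform + extra
    return np.arange(0.0, upper + width, width)


@dataclass(frozen=True)
class NllDistribution:
    """Per-sequence NLLs of one source set, with a normalized histogram."""

    source: str  # "training" | "validation" | "sampled"
    epoch: int
    values: np.ndarray = field(repr=False)
    bin_edges: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values))

    @property
    def histogram(self) -> np.ndarray:
        """Probability mass per bin (out-of-range values clipped to the ends)."""
        clipped = np.clip(
            self.values, self.bin_edges[0], self.bin_edges[-1] - 1e-9
        )
        counts, _ = np.histogram(clipped, bins=self.bin_edges)
        return counts / counts.sum()


def nll_distribution(
    model,
    smiles_set: Sequence[str],
    source: str,
    epoch: int = 0,
    bin_edges: np.ndarray | None = None,
) -> NllDistribution:
    """Score a set of SMILES under ``model`` and wrap the NLLs.

    Sequences with out-of-vocabulary tokens are skipped (their count is
    reported via logging by the caller if needed); an empty set raises.
    """
    if len(smiles_set) == 0:
        raise ValueError("empty SMILES set")
    values, skipped = [], 0
    ok: list[str] = []
    for s in smiles_set:
        try:
            from .tokenizer import encode

            encode(s, model.vocab)
            ok.append(s)
        except (KeyError, ValueError):
            skipped += 1
    if not ok:
        raise ValueError("all sequences were out-of-vocabulary")
    values = model.nll_many(ok)
    if bin_edges is None:
        bin_edges = default_bin_edges(float(np.max(values)) if len(values) else 10.0)
    return NllDistribution(
        source=source, epoch=epoch, values=np.asarray(values), bin_edges=bin_edges
    )


def jensen_shannon(dist_a: NllDistribution, dist_b: NllDistribution) -> float:
    """JSD between two NLL histograms, natural logs, in [0, ln 2].

    ``JSD = KL(A||M)/2 + KL(B||M)/2`` with ``M`` the midpoint mixture; both
    histograms must share the same binning.
    """
    if not np.array_equal(dist_a.bin_edges, dist_b.bin_edges):
        raise ValueError("histograms are on different binnings")
    p = dist_a.histogram + _SMOOTH
    q = dist_b.histogram + _SMOOTH
    p /= p.sum()
    q /= q.sum()
    return float(jensenshannon(p, q, base=np.e) ** 2)


@dataclass(frozen=True)
class EpochDiagnostics:
    epoch: int
    jsd_train_valid: float
    jsd_train_sampled: float
    jsd_valid_sampled: float
    mean_training: float
    mean_validation: float
    mean_sampled: float
    var_training: float
    var_validation: float
    var_sampled: float
    percent_valid_smiles: float = float("nan")

    def __post_init__(self) -> None:
        for j in (self.jsd_train_valid, self.jsd_train_sampled, self.jsd_valid_sampled):
            if not (-1e-9 <= j <= LN2 + 1e-9):
                raise ValueError(f"JSD out of [0, ln 2]: {j}")


def epoch_diagnostics(
    training: NllDistribution,
    validation: NllDistribution,
    sampled: NllDistribution,
    percent_valid_smiles: float = float("nan"),
) -> EpochDiagnostics:
    """Assemble one epoch's diagnostics from the three NLL distributions."""
    return EpochDiagnostics(
        epoch=training.epoch,
        jsd_train_valid=jensen_shannon(training, validation),
        jsd_train_sampled=jensen_shannon(training, sampled),
        jsd_valid_sampled=jensen_shannon(validation, sampled),
        mean_training=training.mean,
        mean_validation=validation.mean,
        mean_sampled=sampled.mean,
        var_training=training.variance,
        var_validation=validation.variance,
        var_sampled=sampled.variance,
        percent_valid_smiles=percent_valid_smiles,
    )


@dataclass(frozen=True)
class DiagnosisReport:
    epochs: tuple[int, ...]
    labels: tuple[str, ...]  # per-epoch: undertrained | converged | overtrained
    recommended_window: tuple[int, int] | None
    converged_window: tuple[int, int] | None

    def label_of(self, epoch: int) -> str:
        return self.labels[self.epochs.index(epoch)]


def _plateau_mask(values: np.ndarray, slope_tol: float, window: int = 3) -> np.ndarray:
    """True where the rolling slope magnitude stays under ``slope_tol``."""
    n = len(values)
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - window + 1)
        seg = values[lo : i + 1]
        if len(seg) >= 2:
            slope = np.polyfit(np.arange(len(seg)), seg, 1)[0]
            mask[i] = abs(slope) <= slope_tol
        else:
            mask[i] = False
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def save_trajectory_plot(
    per_epoch: Sequence["EpochDiagnostics"],
    reference: tuple[float, float],
    out: str,
) -> None:
    """Three-panel training-trajectory figure: JSDs, means, variances.

    The dashed line marks the uniform sampler's reference mean ``ln n``
    (its variance reference is 0).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diags = sorted(per_epoch, key=lambda d: d.epoch)
    ep = [d.epoch for d in diags]
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)
    axes[0].plot(ep, [d.jsd_train_valid for d in diags], label="train/valid")
    axes[0].plot(ep, [d.jsd_train_sampled for d in diags], label="train/sampled")
    axes[0].plot(ep, [d.jsd_valid_sampled for d in diags], label="valid/sampled")
    axes[0].set_ylabel("JSD (nats)")
    axes[0].legend()
    for key, ax in (("mean", axes[1]), ("var", axes[2])):
        for src in ("training", "validation", "sampled"):
            ax.plot(ep, [getattr(d, f"{key}_{src}") for d in diags], label=src)
        ax.set_ylabel(f"NLL {key}")
        ax.legend()
    axes[1].axhline(reference[0], ls="--", c="k", lw=0.8)
    axes[2].axhline(reference[1], ls="--", c="k", lw=0.8)
    axes[2].set_xlabel("epoch")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def diagnose(
    per_epoch: Sequence[EpochDiagnostics],
    reference: tuple[float, float],
    *,
    jsd_tolerance: float = 0.05,
    match_threshold: float = 0.2,
    gap_tolerance: float = 0.1,
    slope_tolerance: float = 0.05,
) -> DiagnosisReport:
    """Stage a training run and recommend an epoch window.

    ``reference`` is the uniform sampler's (mean, variance) = (ln n, 0).
    Labels follow the narrative of the NLL-plot method:

    * *converged* — the three pairwise JSDs sit within ``3 * jsd_tolerance``
      of their joint minimum over the run **and** actually match (every JSD
      below ``match_threshold`` nats);
    * *overtrained* — not converged, and either JSD(valid, sampled) trends up
      while JSD(train, sampled) does not, or the validation-training mean-NLL
      gap is positive (> ``gap_tolerance`` nats) and still growing while the
      training mean still falls (the model keeps fitting the training set at
      held-out expense);
    * *undertrained* — everything before that (including the early phase
      where the sampled set is easier than held-out data).

    The recommended window intersects the converged window, the
    validation-mean plateau nearest ``ln n``, and the low-variance window; if
    the intersection is empty the converged window alone is recommended; with
    no converged epoch the report says so (window ``None``).  Pure function:
    identical inputs give identical reports.
    """
    if len(per_epoch) < 3:
        raise ValueError("need diagnostics for at least 3 epochs")
    diags = sorted(per_epoch, key=lambda d: d.epoch)
    epochs = np.array([d.epoch for d in diags])
    jsd_tv = np.array([d.jsd_train_valid for d in diags])
    jsd_ts = np.array([d.jsd_train_sampled for d in diags])
    jsd_vs = np.array([d.jsd_valid_sampled for d in diags])
    mean_t = np.array([d.mean_training for d in diags])
    mean_v = np.array([d.mean_validation for d in diags])
    mean_s = np.array([d.mean_sampled for d in diags])
    var_v = np.array([d.var_validation for d in diags])
    n_ep = len(diags)

    total = jsd_tv + jsd_ts + jsd_vs
    joint_min = float(total.min())
    worst = np.maximum(jsd_tv, np.maximum(jsd_ts, jsd_vs))
    converged_mask = (total <= joint_min + 3 * jsd_tolerance) & (
        worst <= match_threshold
    )

    # overtraining: sampled keeps closing on train while leaving validation,
    # or the train/valid gap keeps widening while training loss still falls
    gap = mean_v - mean_t
    over_mask = np.zeros(n_ep, dtype=bool)
    w = 3
    for i in range(n_ep):
        lo = max(0, i - w)
        if i - lo < 2 or converged_mask[i]:
            continue
        d_vs = jsd_vs[i] - jsd_vs[lo]
        d_ts = jsd_ts[i] - jsd_ts[lo]
        jsd_trend = d_vs > jsd_tolerance / 2 and d_ts <= jsd_tolerance / 2
        gap_trend = (
            gap[i] > gap_tolerance
            and gap[i] - gap[lo] > jsd_tolerance / 2
            and mean_t[i] < mean_t[lo]
        )
        over_mask[i] = jsd_trend or gap_trend
    # absorbing: once overtrained, later epochs stay overtrained unless the
    # distributions come back into agreement
    for i in range(1, n_ep):
        if over_mask[i - 1] and not converged_mask[i]:
            over_mask[i] = True

    under_mask = (mean_s < np.minimum(mean_t, mean_v) - 1e-9) & ~converged_mask

    labels = []
    for i in range(n_ep):
        if over_mask[i]:
            labels.append("overtrained")
        elif converged_mask[i]:
            labels.append("converged")
        elif under_mask[i]:
            labels.append("undertrained")
        else:
            labels.append("undertrained" if i < n_ep / 2 else "overtrained")

    conv_runs = _runs(np.array([lab == "converged" for lab in labels]))
    converged_window = None
    if conv_runs:
        s, e = max(conv_runs, key=lambda r: r[1] - r[0])
        converged_window = (int(epochs[s]), int(epochs[e]))

    mu_ref, _ = reference
    mean_plateau = _plateau_mask(mean_v, slope_tolerance)
    var_plateau = var_v <= var_v.min() + max(slope_tolerance, 0.25 * (float(np.ptp(var_v)) or 1.0))
    recommended = None
    if converged_window is not None:
        joint = (
            np.array([lab == "converged" for lab in labels])
            & mean_plateau
            & var_plateau
        )
        joint_runs = _runs(joint)
        if joint_runs:
            # among joint runs, prefer the one whose validation mean is
            # nearest the uniform reference ln n
            def dist(run):
                s, e = run
                return abs(float(mean_v[s : e + 1].mean()) - mu_ref)

            s, e = min(joint_runs, key=dist)
            recommended = (int(epochs[s]), int(epochs[e]))
        else:
            recommended = converged_window
    return DiagnosisReport(
        epochs=tuple(int(e) for e in epochs),
        labels=tuple(labels),
        recommended_window=recommended,
        converged_window=converged_window,
    )
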