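"""Scoring sampled SMILES multisets against a reference space.

The central quantities:

* the Euler-diagram partition of a sample — valid / invalid strings,
  strings generated directly in canonical form, molecules inside / outside
  the reference space (by canonical-SMILES intersection), with total and
  unique counts for each;
* the *coverage fraction* ``unique_in_space / n``, reported next to the
  ideal uniform sampler's expected fraction ``1 - (1 - 1/n)^k`` at the same
  sample size, which upper-bounds it in expectation;
* the *frequency spectrum* across ``M`` independently trained models (how
  many models generated each molecule of the space), compared against the
  ``Binomial(M, p_cov)`` null of ``M`` ideal samplers;
* the n-gram composition of the space's canonical SMILES, linking rare
  tokens/bigrams to poorly sampled molecules.
"""

from __future__ import annotations

import sqlite3
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemspace import ReferenceSpace, canonicalize
from .idealmodel import expected_fraction, ideal_frequency_null
from .lm import SampledSequence
from .tokenizer import tokenize, BEGIN, END

__all__ = [
    "SampleReport",
    "FrequencySpectrum",
    "evaluate_sample",
    "frequency_spectrum",
    "frequency_vs_nll",
    "ngram_analysis",
    "SqliteUniqueSet",
]


class SqliteUniqueSet:
    """Disk-backed unique-string set for samples larger than memory.

    Drop-in for the built-in ``set`` where only ``add``, ``__contains__`` and
    ``__len__`` are needed; used by :func:`evaluate_sample` when a path is
    supplied.
    """

    def __init__(self, path: str | Path):
        self._con = sqlite3.connect(str(path))
        self._con.execute("CREATE TABLE IF NOT EXISTS u (s TEXT PRIMARY KEY)")
        self._len = self._con.execute("SELECT COUNT(*) FROM u").fetchone()[0]

    def add(self, s: str) -> None:
        cur = self._con.execute("INSERT OR IGNORE INTO u VALUES (?)", (s,))
        self._len += cur.rowcount

    def __contains__(self, s: str) -> bool:
        return (
            self._con.execute("SELECT 1 FROM u WHERE s = ?", (s,)).fetchone()
            is not None
        )

    def __len__(self) -> int:
        return self._len

    def __iter__(self):
        for (s,) in self._con.execute("SELECT s FROM u"):
            yield s

    def close(self) -> None:
        self._con.commit()
        self._con.close()


@dataclass(frozen=True)
class SampleReport:
    """Partition counts of a sampled SMILES multiset against a space."""

    total: int
    valid: int
    invalid: int
    canonical_as_generated: int
    in_space: int
    out_of_space: int
    unique_valid: int
    unique_in_space: int
    unique_out_of_space: int
    coverage_fraction: float
    ideal_fraction: float
    n: int
    out_of_space_molecules: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        assert self.valid + self.invalid == self.total
        assert self.in_space + self.out_of_space == self.valid
        assert self.canonical_as_generated <= self.valid
        assert self.unique_in_space <= self.n
        assert 0.0 <= self.coverage_fraction <= 1.0

    @property
    def ideal_gap(self) -> float:
        """Ideal expected coverage minus achieved coverage (>= 0 in expectation)."""
        return self.ideal_fraction - self.coverage_fraction

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "valid": self.valid,
            "invalid": self.invalid,
            "canonical_as_generated": self.canonical_as_generated,
            "in_space": self.in_space,
            "out_of_space": self.out_of_space,
            "unique_valid": self.unique_valid,
            "unique_in_space": self.unique_in_space,
            "unique_out_of_space": self.unique_out_of_space,
            "coverage_fraction": self.coverage_fraction,
            "ideal_fraction": self.ideal_fraction,
            "ideal_gap": self.ideal_gap,
            "n": self.n,
        }


def evaluate_sample(
    sample: Iterable[str | SampledSequence],
    space: ReferenceSpace,
    k: int | None = None,
    *,
    unique_store_path: str | Path | None = None,
    keep_out_of_space: bool = True,
) -> SampleReport:
    """Classify every sampled string once and measure coverage.

    ``sample`` may be any iterable (a generator is fine: processing is
    streaming, and unique molecules can be tracked on disk via
    ``unique_store_path`` for samples larger than memory).  Strings that do
    not parse are invalid; :class:`~chemcover.lm.SampledSequence` records
    flagged as truncated are counted invalid without parsing.  Molecule-level
    uniqueness is by canonical SMILES.  ``k`` defaults to the observed sample
    size and feeds the ideal-fraction comparison.
    """
    total = valid = canonical_as_gen = in_space = out_space = 0
    if unique_store_path is not None:
        uniq_in: set | SqliteUniqueSet = SqliteUniqueSet(unique_store_path)
    else:
        uniq_in = set()
    uniq_out: Counter[str] = Counter()
    uniq_valid: set[str] = set()
    for item in sample:
        if isinstance(item, SampledSequence):
            raw, truncated = item.smiles, item.truncated
        else:
            raw, truncated = item, False
        total += 1
        canon = None if truncated else canonicalize(raw)
        if canon is None:
            continue
        valid += 1
        uniq_valid.add(canon)
        if raw == canon:
            canonical_as_gen += 1
        if canon in space:
            in_space += 1
            uniq_in.add(canon)
        else:
            out_space += 1
            uniq_out[canon] += 1
    if total == 0:
        raise ValueError("empty sample")
    if k is None:
        k = total
    n_unique_in = len(uniq_in)
    if isinstance(uniq_in, SqliteUniqueSet):
        uniq_in.close()
    return SampleReport(
        total=total,
        valid=valid,
        invalid=total - valid,
        canonical_as_generated=canonical_as_gen,
        in_space=in_space,
        out_of_space=out_space,
        unique_valid=len(uniq_valid),
        unique_in_space=n_unique_in,
        unique_out_of_space=len(uniq_out),
        coverage_fraction=n_unique_in / space.n,
        ideal_fraction=expected_fraction(space.n, k) if k > 1 else 0.0,
        n=space.n,
        out_of_space_molecules=dict(uniq_out) if keep_out_of_space else {},
    )


@dataclass(frozen=True)
class FrequencySpectrum:
    """Per-molecule generation frequency across M independent models."""

    num_models: int
    k: int
    frequencies: dict[str, int] = field(repr=False)  # every molecule of the space
    n: int = 0

    def __post_init__(self) -> None:
        if any(not (0 <= f <= self.num_models) for f in self.frequencies.values()):
            raise ValueError("frequencies out of range")

    @property
    def histogram(self) -> np.ndarray:
        """Counts of molecules at each frequency 0..M; sums to n."""
        h = np.zeros(self.num_models + 1, dtype=np.int64)
        for f in self.frequencies.values():
            h[f] += 1
        return h

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.frequencies.values())))

    @property
    def mode(self) -> int:
        return int(np.argmax(self.histogram))

    @property
    def never_sampled_count(self) -> int:
        return int(self.histogram[0])

    def ideal_null(self):
        """The matching Binomial(M, p_cov) null of M ideal samplers."""
        return ideal_frequency_null(self.num_models, self.n, self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.frequencies.items()), columns=["smiles", "frequency"]
        )


def frequency_spectrum(
    samples_by_model: Sequence[Iterable[str]],
    space: ReferenceSpace,
    k: int,
) -> FrequencySpectrum:
    """Count, for every molecule of the space, how many models generated it.

    Each element of ``samples_by_model`` must already be deduplicated and
    intersected with the space (the unique-in-space set of one model's
    sample); a molecule outside the space raises.  ``k`` is the per-model
    sample size, carried along for the binomial null.
    """
    if len(samples_by_model) < 1:
        raise ValueError("need at least one model")
    freq = {mol: 0 for mol in space.molecules}
    for m, sample in enumerate(samples_by_model):
        seen = set(sample)
        extra = seen - space.molecules
        if extra:
            raise ValueError(
                f"model {m}: {len(extra)} molecules not in space "
                f"(e.g. {sorted(extra)[:3]})"
            )
        for mol in seen:
            freq[mol] += 1
    return FrequencySpectrum(
        num_models=len(samples_by_model), k=k, frequencies=freq, n=space.n
    )


def frequency_vs_nll(
    spectrum: FrequencySpectrum,
    mean_nll_per_molecule: Mapping[str, float],
) -> pd.DataFrame:
    """Stratify mean NLL by frequency; rank correlation attached as ``.attrs``.

    Generation frequency should be strongly negatively rank-correlated with
    mean NLL: molecules the models consider improbable are rarely produced.
    Returns one row per occupied frequency stratum (count, mean/median NLL);
    ``result.attrs["spearman_rho"]`` holds Spearman's rho over molecules with
    an NLL (``nan`` when fewer than two strata are occupied).
    """
    rows = []
    pairs = [
        (f, mean_nll_per_molecule[mol])
        for mol, f in spectrum.frequencies.items()
        if mol in mean_nll_per_molecule
    ]
    if not pairs:
        raise ValueError("no molecule has an NLL")
    arr = np.array(pairs)
    for f in range(spectrum.num_models + 1):
        sel = arr[arr[:, 0] == f, 1]
        if sel.size == 0:
            continue  # empty stratum skipped
        rows.append(
            {
                "frequency": f,
                "count": int(sel.size),
                "mean_nll": float(sel.mean()),
                "median_nll": float(np.median(sel)),
                "std_nll": float(sel.std()),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        rho = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
    else:
        rho = float("nan")  # single stratum: correlation undefined
    out.attrs["spearman_rho"] = rho
    return out


def ngram_analysis(
    space: ReferenceSpace,
    spectrum: FrequencySpectrum | None,
    order: int,
    *,
    include_boundary: bool = False,
) -> pd.DataFrame:
    """n-gram composition of the space's canonical SMILES (order 1 or 2).

    Tokens follow the model tokenizer's rules.  For order 1 the ``^``/``$``
    markers are excluded; for order 2 boundary grams (``^C``, ``C$``) are
    included only when ``include_boundary`` is set.  Each gram row carries
    its count, percent of all grams, and — when a frequency spectrum is
    given — the mean generation frequency of the molecules containing it.
    Sorted by percent descending.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    counts: Counter[str] = Counter()
    gram_mols: dict[str, list[str]] = {}
    for mol in space.molecules:
        toks = tokenize(mol)
        if order == 2 and include_boundary:
            toks = [BEGIN, *toks, END]
        grams = (
            toks
            if order == 1
            else ["".join(toks[i : i + 2]) for i in range(len(toks) - 1)]
        )
        for g in grams:
            counts[g] += 1
        for g in set(grams):
            gram_mols.setdefault(g, []).append(mol)
    total = sum(counts.values())
    rows = []
    for g, cnt in counts.items():
        row = {"gram": g, "count": cnt, "percent": 100.0 * cnt / total}
        if spectrum is not None:
            row["mean_frequency"] = float(
                np.mean([spectrum.frequencies[m] for m in gram_mols[g]])
            )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["percent", "gram"], ascending=[False, True], ignore_index=True
    )
    return out
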