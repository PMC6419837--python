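"""Annotating out-of-space molecules with the constraints they break.

Every valid molecule a model generates *outside* the reference space must
violate at least one property that defined the space's enumeration — too
many heavy atoms, a foreign element, a graph topology absent from the space,
a disallowed functional group, and so on.  When nothing applies the molecule
is *miscellaneous*: either the space's enumeration was not exhaustive or the
canonical dialects of two toolkits disagree.  Tautomer detection needs a
tautomer enumerator, so it is a pluggable hook: pass a callable returning a
molecule's tautomers as SMILES and any tautomer found in the space yields
the ``tautomer_of_member`` label; without a hook the category is simply not
evaluated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .chemspace import (
    EnumerationFilters,
    ReferenceSpace,
    canonicalize,
    carbon_skeleton,
    check_filters,
)

__all__ = ["ViolationRecord", "label_molecule", "violation_summary", "MISCELLANEOUS"]

MISCELLANEOUS = "miscellaneous"
TautomerHook = Callable[[str], Iterable[str]]


@dataclass(frozen=True)
class ViolationRecord:
    """One out-of-space molecule and every constraint label it carries."""

    smiles: str
    labels: tuple[str, ...]

    @property
    def num_labels(self) -> int:
        return len(self.labels)


def label_molecule(
    smiles: str,
    filters: EnumerationFilters,
    space: ReferenceSpace,
    tautomer_hook: TautomerHook | None = None,
) -> ViolationRecord:
    """All constraint labels of a valid molecule that is not in the space.

    Labels are not prioritized: a molecule can break several constraints and
    every applicable label is recorded.  A molecule that is actually a member
    of the space is mis-routed input and raises.  Deterministic: identical
    inputs always produce identical records.
    """
    canon = canonicalize(smiles)
    if canon is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    if canon in space:
        raise ValueError(f"{canon!r} is in the space; labelling is for outsiders")
    labels = list(check_filters(canon, filters, space=None))
    if carbon_skeleton(canon) not in space.skeletons:
        labels.append("graph_topology")
    if tautomer_hook is not None:
        try:
            tautomers = {canonicalize(t) for t in tautomer_hook(canon)}
        except Exception as exc:  # hook is third-party code
            raise RuntimeError(f"tautomer hook failed on {canon!r}") from exc
        if any(t in space for t in tautomers if t is not None and t != canon):
            labels.append("tautomer_of_member")
    if not labels:
        labels.append(MISCELLANEOUS)
    return ViolationRecord(smiles=canon, labels=tuple(labels))


def violation_summary(records: Sequence[ViolationRecord]) -> dict:
    """Per-label percents and the broken-count histogram.

    Percents may sum over 100 because a molecule can break more than one
    constraint.  The histogram of ``num_labels`` never has mass at 0 — the
    miscellaneous fallback guarantees at least one label per record.
    """
    if not records:
        raise ValueError("no violation records")
    label_counts: Counter[str] = Counter()
    for rec in records:
        for lab in set(rec.labels):
            label_counts[lab] += 1
    m = len(records)
    percents = {
        lab: 100.0 * cnt / m
        for lab, cnt in sorted(label_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    num_labels = np.array([rec.num_labels for rec in records])
    hist = np.bincount(num_labels, minlength=2)
    return {
        "num_molecules": m,
        "percent_by_label": percents,
        "broken_count_histogram": {int(i): int(c) for i, c in enumerate(hist) if i > 0 and c},
    }
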