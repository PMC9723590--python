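"""Species-level aggregation of the sample-by-ASV table.

Phylosymbiosis tests compare one microbial community per host species
with the host phylogeny, so the sample-level table must be reduced to a
species-level table.  Two schemes are provided:

* ``mean_ceiling`` — one table whose entry for (species, ASV) is the
  ceiling of the mean count over that species' samples;
* ``random_pick`` — replicate tables, each picking one sample per
  species at random; a species with at least as many samples as
  replicates contributes a different sample to every replicate, smaller
  species recycle samples as evenly as possible.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np

from .data_model import AsvTable, SampleInfo, derive_seed

__all__ = ["mean_ceiling", "random_pick"]


def _species_groups(table: AsvTable, meta: Iterable[SampleInfo]) -> dict[str, list[str]]:
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    groups: dict[str, list[str]] = {}
    for s in table.sample_ids:
        info = by_id[s]
        if info.is_control:
            continue
        groups.setdefault(info.host_species, []).append(s)
    return groups


def mean_ceiling(table: AsvTable, meta: Iterable[SampleInfo]) -> AsvTable:
    """Average each ASV's count within species and round up ("mean ceiling").

    Returns an :class:`AsvTable` with one row per host species.  The
    ceiling keeps every ASV observed in any of a species' samples present
    in the species-level community.
    """
    groups = _species_groups(table, list(meta))
    if not groups:
        raise ValueError("no non-control samples to aggregate")
    rows = []
    species = []
    index = {s: i for i, s in enumerate(table.sample_ids)}
    for sp in groups:
        samples = groups[sp]
        if not samples:
            warnings.warn(f"species {sp!r} has no samples; excluded")
            continue
        mean = table.counts[[index[s] for s in samples]].mean(axis=0)
        rows.append(np.ceil(mean - 1e-12).astype(np.int64))
        species.append(sp)
    return AsvTable(np.asarray(rows), species, table.asv_ids)


def random_pick(
    table: AsvTable,
    meta: Iterable[SampleInfo],
    n_replicates: int = 10,
    seed: int = 0,
) -> list[AsvTable]:
    """Build replicate species tables by picking one sample per species.

    For a species with ``s`` samples and ``n = n_replicates``:

    * ``s >= n`` — ``n`` distinct samples, no reuse across replicates
      (picking without replacement);
    * ``s < n`` — every sample is used either ``floor(n/s)`` or
      ``ceil(n/s)`` times, with the assignment to replicates randomized.

    Deterministic for a fixed ``seed``, independent of sample order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    meta = list(meta)
    groups = _species_groups(table, meta)
    if not groups:
        raise ValueError("no non-control samples to aggregate")
    index = {s: i for i, s in enumerate(table.sample_ids)}
    assignments: dict[str, list[str]] = {}
    for sp, samples in groups.items():
        rng = np.random.default_rng(derive_seed(seed, f"random_pick:{sp}"))
        samples = sorted(samples)
        s = len(samples)
        if s >= n_replicates:
            picks = list(rng.choice(samples, size=n_replicates, replace=False))
        else:
            reps = math.ceil(n_replicates / s)
            pool: list[str] = []
            for _ in range(reps):
                pool.extend(rng.permutation(samples))
            picks = pool[:n_replicates]
            rng.shuffle(picks)
        assignments[sp] = [str(p) for p in picks]
    species = list(groups)
    out = []
    for r in range(n_replicates):
        rows = np.asarray(
            [table.counts[index[assignments[sp][r]]] for sp in species], dtype=np.int64
        )
        out.append(AsvTable(rows, species, table.asv_ids))
    return out
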