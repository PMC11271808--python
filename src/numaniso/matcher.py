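"""Pool generation and radial-tangential display matching.

Displays are paired across arrangements at identical numerosity, greedily
minimizing Euclidean distance in z-scored property space.  A pair is only
accepted when every property's standardized mean difference (SMD, the
z-score gap) stays within a cap, 0.2 SD by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .generator import Display, GeneratorConfig, generate_display
from .properties import PROPERTY_NAMES, PropertyVector, compute_properties

__all__ = [
    "PooledDisplay",
    "DisplayPool",
    "MatchedPair",
    "MatchReport",
    "DEFAULT_MAX_SMD",
    "generate_pool",
    "match_displays",
]

DEFAULT_MAX_SMD = 0.2


@dataclass(frozen=True)
class PooledDisplay:
    id: int
    display: Display
    properties: PropertyVector


@dataclass(frozen=True)
class DisplayPool:
    displays: tuple[PooledDisplay, ...]
    seed: int

    def by_arrangement(self, arrangement: str) -> list[PooledDisplay]:
        return [p for p in self.displays if p.display.arrangement == arrangement]


@dataclass(frozen=True)
class MatchedPair:
    radial_id: int
    tangential_id: int
    numerosity: int
    smd: dict[str, float]
    distance: float


@dataclass(frozen=True)
class MatchReport:
    pairs: tuple[MatchedPair, ...]
    per_property_smd: dict[str, float]
    pool_sizes: dict[str, int]
    unmatched: tuple[int, ...]
    max_smd: float


def generate_pool(
    config: GeneratorConfig, n_per_arrangement: int, seed: int
) -> DisplayPool:
    """Generate ``n_per_arrangement`` displays per arrangement.

    Per-display seeds are derived deterministically from the pool seed, and
    each display is stored with its property vector.
    """
    if n_per_arrangement < 1:
        raise ValueError("need at least one display per arrangement")
    pooled: list[PooledDisplay] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_arrangement)
    idx = 0
    for arrangement in ("radial", "tangential"):
        for _ in range(n_per_arrangement):
            child_seed = int(children[idx].generate_state(1)[0])
            cfg = dc_replace(config, arrangement=arrangement, seed=child_seed)
            display = generate_display(cfg)
            pooled.append(
                PooledDisplay(idx, display, compute_properties(display))
            )
            idx += 1
    return DisplayPool(tuple(pooled), seed)


def _zscore_table(pool: DisplayPool) -> dict[int, np.ndarray]:
    mat = np.array([p.properties.as_array() for p in pool.displays])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(mat) > 1 else np.ones(mat.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    return {p.id: (mat[i] - mean) / sd for i, p in enumerate(pool.displays)}


def match_displays(
    pool: DisplayPool,
    target_numerosities: list[int] | None = None,
    max_smd: float = DEFAULT_MAX_SMD,
) -> MatchReport:
    """Greedily pair radial with tangential displays of equal numerosity.

    For each target numerosity, radial displays (in id order) claim the
    unused tangential display with the smallest Euclidean distance in
    z-scored property space among candidates whose per-property |z-gap|
    does not exceed ``max_smd``; ties break toward the lower id.  Radial
    displays with no admissible candidate are reported unmatched.
    Displays themselves are never altered.
    """
    radial = pool.by_arrangement("radial")
    tangential = pool.by_arrangement("tangential")
    z = _zscore_table(pool)

    if target_numerosities is None:
        target_numerosities = sorted(
            {p.display.numerosity for p in radial}
            & {p.display.numerosity for p in tangential}
        )

    pairs: list[MatchedPair] = []
    unmatched: list[int] = []
    used: set[int] = set()
    for n in target_numerosities:
        r_candidates = [p for p in radial if p.display.numerosity == n]
        for r in sorted(r_candidates, key=lambda p: p.id):
            best: tuple[float, int] | None = None
            for t in tangential:
                if t.id in used or t.display.numerosity != n:
                    continue
                gap = np.abs(z[r.id] - z[t.id])
                if np.any(gap > max_smd):
                    continue
                dist = float(np.linalg.norm(z[r.id] - z[t.id]))
                key = (dist, t.id)
                if best is None or key < best:
                    best = key
            if best is None:
                unmatched.append(r.id)
                continue
            dist, t_id = best
            used.add(t_id)
            gap = np.abs(z[r.id] - z[t_id])
            pairs.append(
                MatchedPair(
                    radial_id=r.id,
                    tangential_id=t_id,
                    numerosity=n,
                    smd=dict(zip(PROPERTY_NAMES, gap.tolist())),
                    distance=dist,
                )
            )

    matched_nums = {p.numerosity for p in pairs}
    for r in radial:
        if r.display.numerosity not in set(target_numerosities):
            unmatched.append(r.id)
    for t in tangential:
        if t.id not in used and t.display.numerosity not in matched_nums:
            unmatched.append(t.id)

    if pairs:
        per_prop = {
            name: float(np.mean([p.smd[name] for p in pairs]))
            for name in PROPERTY_NAMES
        }
    else:
        per_prop = {name: float("nan") for name in PROPERTY_NAMES}
    return MatchReport(
        pairs=tuple(pairs),
        per_property_smd=per_prop,
        pool_sizes={"radial": len(radial), "tangential": len(tangential)},
        unmatched=tuple(sorted(set(unmatched))),
        max_smd=max_smd,
    )
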