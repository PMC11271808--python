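"""Construction of radial and tangential disc displays.

A display is built in four stages: base discs are packed by rejection
sampling under the constraint that no two base discs' interference zones
overlap; each base is then allocated a configuration (single, pair or
triplet); flanking discs are sampled inside the designated zone of their
base (radial zone for radial displays, tangential for tangential ones,
never in the central overlap lens); finally contrast polarity is assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import (
    EllipseZone,
    Point,
    ellipse_bbox_halfwidths,
    ellipses_overlap,
    eccentricity,
    in_zone_overlap,
    make_zones,
    point_in_ellipse,
)

__all__ = [
    "Disc",
    "GeneratorConfig",
    "Display",
    "FIELD_SIZES",
    "pack_base_discs",
    "allocate_configurations",
    "place_flankers",
    "assign_polarity",
    "generate_display",
    "validate_display",
]

Arrangement = Literal["radial", "tangential"]
Polarity = Literal["dark", "light"]
Role = Literal["base", "flanker"]

#: Field rectangle sizes in degrees (width, height), fixation at the center.
FIELD_SIZES: dict[str, tuple[float, float]] = {
    "small": (21.5, 13.5),
    "large": (27.0, 18.5),
}

PERCENT_PAIR_LEVELS = (0, 25, 50, 75, 100)


@dataclass(frozen=True)
class Disc:
    """A positioned circular stimulus element."""

    id: int
    center: Point
    radius: float
    polarity: Polarity
    role: Role
    parent_id: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the display generator."""

    arrangement: Arrangement = "radial"
    mode: Literal["mixture", "all_triplets"] = "mixture"
    percent_pairs: int | None = 50
    polarity_scheme: Literal["uniform_dark", "uniform_light", "mixed"] = "uniform_dark"
    field: str | tuple[float, float] = "small"
    disc_radius: float = 0.36
    # Zone extent is 0.25 x eccentricity along the radial axis on EACH side
    # of the disc (0.1 x tangentially), i.e. full axes of 0.5 and 0.2 times
    # eccentricity.  This is the calibration under which base packing
    # saturates at the documented 17-22 (small field) base-disc counts;
    # halving the factors quadruples the counts.
    zone_major_factor: float = 0.5
    zone_minor_factor: float = 0.2
    fixation_exclusion_radius: float = 4.0
    #: require the designated zone (the one that will host flankers) to lie
    #: inside the field rectangle inset by the disc radius, so flankers
    #: always have field-legal candidate positions.  The rotated zone is a
    #: spacing constraint only and may overhang the field edge.
    zones_within_field: bool = True
    seed: int = 0
    max_consecutive_failures: int = 3000

    def __post_init__(self) -> None:
        if self.arrangement not in ("radial", "tangential"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.mode not in ("mixture", "all_triplets"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "mixture":
            if self.percent_pairs not in PERCENT_PAIR_LEVELS:
                raise ValueError(
                    f"percent_pairs must be one of {PERCENT_PAIR_LEVELS}, "
                    f"got {self.percent_pairs!r}"
                )
        elif self.percent_pairs is not None:
            raise ValueError("percent_pairs applies to mixture mode only")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field dimensions must be positive")
        if not 0 < self.zone_minor_factor <= self.zone_major_factor < 1:
            raise ValueError("zone factors must satisfy 0 < minor <= major < 1")

    @property
    def field_size(self) -> tuple[float, float]:
        if isinstance(self.field, str):
            try:
                return FIELD_SIZES[self.field]
            except KeyError:
                raise ValueError(f"unknown field name {self.field!r}") from None
        w, h = self.field
        return float(w), float(h)


@dataclass(frozen=True)
class Display:
    """A complete stimulus: discs plus construction metadata."""

    discs: tuple[Disc, ...]
    arrangement: Arrangement
    mode: str
    percent_pairs: int | None
    polarity_scheme: str
    base_count: int
    seed: int
    field: tuple[float, float]
    disc_radius: float
    fixation_exclusion_radius: float = 4.0
    zone_major_factor: float = 0.5
    zone_minor_factor: float = 0.2
    zones_within_field: bool = True
    demotions: tuple[str, ...] = field(default_factory=tuple)
    side_fallbacks: tuple[str, ...] = field(default_factory=tuple)

    @property
    def numerosity(self) -> int:
        return len(self.discs)

    @property
    def bases(self) -> tuple[Disc, ...]:
        return tuple(d for d in self.discs if d.role == "base")

    @property
    def flankers(self) -> tuple[Disc, ...]:
        return tuple(d for d in self.discs if d.role == "flanker")

    def centers(self) -> np.ndarray:
        return np.array([[d.center.x, d.center.y] for d in self.discs])


def _disc_fits_field(
    x: float, y: float, radius: float, w: float, h: float, exclusion: float
) -> bool:
    # whole disc inside the rectangle and wholly outside the exclusion circle
    if abs(x) > w / 2 - radius or abs(y) > h / 2 - radius:
        return False
    return math.hypot(x, y) >= exclusion + radius


def pack_base_discs(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[Disc]:
    """Pack base discs by uniform rejection sampling.

    A candidate is accepted when neither of its two zones overlaps any zone
    (of either orientation) of an already accepted base and its disc does
    not overlap an accepted disc.  Sampling stops after
    ``max_consecutive_failures`` successive rejections, the operational
    proxy for "no further disc fits".
    """
    w, h = config.field_size
    r = config.disc_radius
    excl = config.fixation_exclusion_radius
    if w / 2 - r <= 0 or h / 2 - r <= 0:
        return []

    bases: list[Disc] = []
    zones: list[tuple[EllipseZone, EllipseZone]] = []
    # parallel arrays for the cheap distance prefilter
    cx: list[float] = []
    cy: list[float] = []
    semi_major: list[float] = []
    semi_minor: list[float] = []

    failures = 0
    while failures < config.max_consecutive_failures:
        x = rng.uniform(-w / 2 + r, w / 2 - r)
        y = rng.uniform(-h / 2 + r, h / 2 - r)
        if math.hypot(x, y) < excl + r:
            failures += 1
            continue
        center = Point(x, y)
        zr, zt = make_zones(center, config.zone_major_factor, config.zone_minor_factor)
        designated = zr if config.arrangement == "radial" else zt
        if config.zones_within_field and not _zone_fits_field(designated, x, y, w, h, r):
            failures += 1
            continue
        # all-triplet displays need two flankers per base; reject bases
        # whose zone cannot host one on the fixation side
        if config.mode == "all_triplets" and not inward_flanker_feasible(
            math.hypot(x, y), config
        ):
            failures += 1
            continue
        if _conflicts(center, zr, zt, r, bases, zones, cx, cy, semi_major, semi_minor):
            failures += 1
            continue
        disc_id = len(bases)
        bases.append(Disc(disc_id, center, r, "dark", "base", disc_id))
        zones.append((zr, zt))
        cx.append(x)
        cy.append(y)
        semi_major.append(zr.semi_major)
        semi_minor.append(zr.semi_minor)
        failures = 0
    return bases


def _zone_fits_field(
    z: EllipseZone, x: float, y: float, w: float, h: float, disc_radius: float
) -> bool:
    """Zone inside the field rectangle inset by the disc radius.

    The inset guarantees that any zone point is a field-legal flanker
    center.
    """
    hw, hh = ellipse_bbox_halfwidths(z)
    return abs(x) + hw <= w / 2 - disc_radius and abs(y) + hh <= h / 2 - disc_radius


def inward_flanker_feasible(ecc: float, config: GeneratorConfig) -> bool:
    """Can a flanker disc sit on the fixation side of a radial zone?

    Probes a grid over the inward half of the radial zone for a point that
    clears the central overlap lens, keeps the flanker disc separated from
    the base disc, and keeps the whole flanker outside the fixation
    exclusion circle.  Bases closer than roughly 5 degrees to fixation
    (at default parameters) admit no such point; a radial triplet there
    cannot have one flanker on each side.  Tangential zones are never
    limited this way (sideways offsets do not reduce eccentricity), so the
    test only concerns radial arrangements.
    """
    a = config.zone_major_factor * ecc / 2.0
    b = config.zone_minor_factor * ecc / 2.0
    lens = b  # rotated zone's semi-minor bounds the lens along the major axis
    r = config.disc_radius
    inner = config.fixation_exclusion_radius + r
    u = np.linspace(0.0, a, 48)[1:]
    v = np.linspace(-b, b, 25)
    uu, vv = np.meshgrid(u, v)
    ok = (
        ((uu / a) ** 2 + (vv / b) ** 2 <= 1.0)
        & ((uu / lens) ** 2 + (vv / a) ** 2 > 1.0)
        & (uu**2 + vv**2 >= (2.0 * r) ** 2)
        & ((ecc - uu) ** 2 + vv**2 >= inner**2)
    )
    return bool(np.any(ok))


def _conflicts(
    center: Point,
    zr: EllipseZone,
    zt: EllipseZone,
    radius: float,
    bases: list[Disc],
    zones: list[tuple[EllipseZone, EllipseZone]],
    cx: list[float],
    cy: list[float],
    semi_major: list[float],
    semi_minor: list[float],
) -> bool:
    if not bases:
        return False
    dx = np.asarray(cx) - center.x
    dy = np.asarray(cy) - center.y
    dist = np.hypot(dx, dy)
    if np.any(dist < 2 * radius):
        return True
    a = np.asarray(semi_major)
    b = np.asarray(semi_minor)
    # definitely overlapping: even the minor axes cannot separate
    if np.any(dist <= b + zr.semi_minor):
        return True
    # only bases within reach of the two major axes need the exact test
    for i in np.nonzero(dist <= a + zr.semi_major)[0]:
        ozr, ozt = zones[int(i)]
        for cand in (zr, zt):
            if ellipses_overlap(cand, ozr) or ellipses_overlap(cand, ozt):
                return True
    return False


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def allocate_configurations(
    base_count: int, percent_pairs: int, rng: np.random.Generator
) -> list[str]:
    """Assign each base a configuration: ``pair``, ``triplet`` or ``single``.

    ``percent_pairs`` of the bases are paired; the remainder is split
    exactly in half between triplets and singles.  When the remainder is
    odd, the pair count is moved by one (up for percent_pairs >= 50, down
    otherwise) so the equal split is possible; this keeps the flanker
    total equal to the base count, hence numerosity = 2 x base_count.
    """
    if percent_pairs not in PERCENT_PAIR_LEVELS:
        raise ValueError(
            f"percent_pairs must be one of {PERCENT_PAIR_LEVELS}, got {percent_pairs!r}"
        )
    if base_count < 1:
        raise ValueError("need at least one base disc")
    n_pair = _round_half_up(percent_pairs * base_count / 100.0)
    if (base_count - n_pair) % 2 == 1:
        step = 1 if percent_pairs >= 50 else -1
        if not 0 <= n_pair + step <= base_count:
            step = -step
        n_pair += step
    n_half = (base_count - n_pair) // 2
    roles = ["pair"] * n_pair + ["triplet"] * n_half + ["single"] * n_half
    rng.shuffle(roles)
    return roles


def _assign_roles_feasibly(
    bases: Sequence[Disc],
    roles: Sequence[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Redistribute allocated roles so triplets land on feasible bases.

    Radial arrangements only: a triplet needs a flanker on the fixation
    side, which bases near the exclusion circle cannot host.  Triplet
    roles are drawn uniformly among feasible bases; when there are more
    triplets than feasible bases, a triplet plus a single convert into two
    pairs (both moves keep the flanker total equal to the base count).
    """
    roles = list(roles)
    if config.arrangement != "radial" or "triplet" not in roles:
        return roles
    n_tri = roles.count("triplet")
    n_pair = roles.count("pair")
    n_single = roles.count("single")
    feasible = [
        i
        for i, b in enumerate(bases)
        if inward_flanker_feasible(eccentricity(b.center), config)
    ]
    excess = max(0, n_tri - len(feasible))
    swap = min(excess, n_single)
    n_tri -= swap
    n_single -= swap
    n_pair += 2 * swap
    out: list[str | None] = [None] * len(bases)
    if n_tri:
        for i in rng.choice(feasible, size=n_tri, replace=False):
            out[int(i)] = "triplet"
    others = ["pair"] * n_pair + ["single"] * n_single
    rng.shuffle(others)
    rest = iter(others)
    for i in range(len(bases)):
        if out[i] is None:
            out[i] = next(rest)
    return out  # type: ignore[return-value]


def _sample_in_half_zone(
    zone: EllipseZone, side: int, rng: np.random.Generator
) -> Point:
    """Uniform sample in the half of ``zone`` on the given side of its center."""
    while True:
        rho = math.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u = zone.semi_major * rho * math.cos(phi)
        v = zone.semi_minor * rho * math.sin(phi)
        if u * side <= 0:
            u = -u
        c, s = math.cos(zone.orientation), math.sin(zone.orientation)
        return Point(zone.center.x + c * u - s * v, zone.center.y + s * u + c * v)


def place_flankers(
    bases: Sequence[Disc],
    roles: Sequence[str],
    arrangement: Arrangement,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[Disc], list[str], list[str]]:
    """Sample flanker positions inside each base's designated zone.

    Pairs get one flanker on a uniformly chosen side of the base along the
    zone's major axis; triplets get one on each side.  A flanker must stay
    out of the two zones' overlap lens, inside the field, outside the
    fixation exclusion and clear of every other disc.  When a side admits
    no legal position within the failure budget the flanker falls back to
    the opposite side (keeping the disc count intact; recorded as a side
    fallback); only if both sides fail is the base demoted
    (triplet -> pair -> single).

    Returns ``(flankers, demotions, side_fallbacks)``.
    """
    if len(bases) != len(roles):
        raise ValueError("one role per base required")
    w, h = config.field_size
    r = config.disc_radius
    excl = config.fixation_exclusion_radius

    placed: list[Disc] = []
    demotions: list[str] = []
    fallbacks: list[str] = []
    all_x = [b.center.x for b in bases]
    all_y = [b.center.y for b in bases]

    next_id = len(bases)
    for base, role in zip(bases, roles):
        if role == "single":
            continue
        zr, zt = make_zones(
            base.center, config.zone_major_factor, config.zone_minor_factor
        )
        designated, other = (zr, zt) if arrangement == "radial" else (zt, zr)
        if role == "pair":
            sides = [1 if rng.uniform() < 0.5 else -1]
        elif role == "triplet":
            sides = [1, -1]
        else:
            raise ValueError(f"unknown role {role!r}")

        n_placed = 0
        for side in sides:
            pos = _try_place(
                designated, other, side, base, r, w, h, excl,
                all_x, all_y, config.max_consecutive_failures, rng,
            )
            if pos is None:
                pos = _try_place(
                    designated, other, -side, base, r, w, h, excl,
                    all_x, all_y, config.max_consecutive_failures, rng,
                )
                if pos is not None:
                    fallbacks.append(
                        f"base {base.id}: side {side:+d} -> {-side:+d}"
                    )
            if pos is None:
                continue
            placed.append(Disc(next_id, pos, r, "dark", "flanker", base.id))
            all_x.append(pos.x)
            all_y.append(pos.y)
            next_id += 1
            n_placed += 1
        if n_placed < len(sides):
            demoted_to = {0: "single", 1: "pair"}[n_placed]
            demotions.append(f"base {base.id}: {role} -> {demoted_to}")
    return placed, demotions, fallbacks


def _try_place(
    designated: EllipseZone,
    other: EllipseZone,
    side: int,
    base: Disc,
    radius: float,
    w: float,
    h: float,
    excl: float,
    all_x: list[float],
    all_y: list[float],
    max_failures: int,
    rng: np.random.Generator,
) -> Point | None:
    xs = np.asarray(all_x)
    ys = np.asarray(all_y)
    for _ in range(max_failures):
        p = _sample_in_half_zone(designated, side, rng)
        if other.contains(p):  # central overlap lens is off limits
            continue
        if not _disc_fits_field(p.x, p.y, radius, w, h, excl):
            continue
        if np.min(np.hypot(xs - p.x, ys - p.y)) < 2 * radius:
            continue
        return p
    return None


def assign_polarity(discs: Sequence[Disc], scheme: str) -> list[Disc]:
    """Recolor discs without moving them.

    ``uniform_dark`` / ``uniform_light`` color every disc; ``mixed`` makes
    bases dark and flankers light.
    """
    if scheme == "uniform_dark":
        return [replace(d, polarity="dark") for d in discs]
    if scheme == "uniform_light":
        return [replace(d, polarity="light") for d in discs]
    if scheme == "mixed":
        return [
            replace(d, polarity="dark" if d.role == "base" else "light")
            for d in discs
        ]
    raise ValueError(f"unknown polarity scheme {scheme!r}")


def generate_display(
    config: GeneratorConfig, base_count: int | None = None
) -> Display:
    """Run the full construction pipeline for one display.

    With ``base_count`` given, packing is re-run with derived seeds until
    at least that many bases fit and the first ``base_count`` accepted
    bases are kept (any prefix of a legal packing is itself legal).
    """
    rng = np.random.default_rng(config.seed)
    if base_count is None:
        bases = pack_base_discs(config, rng)
    else:
        bases = _pack_exact(config, base_count)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if not bases:
        return Display(
            discs=(),
            arrangement=config.arrangement,
            mode=config.mode,
            percent_pairs=config.percent_pairs,
            polarity_scheme=config.polarity_scheme,
            base_count=0,
            seed=config.seed,
            field=config.field_size,
            disc_radius=config.disc_radius,
            fixation_exclusion_radius=config.fixation_exclusion_radius,
            zone_major_factor=config.zone_major_factor,
            zone_minor_factor=config.zone_minor_factor,
            zones_within_field=config.zones_within_field,
        )
    if config.mode == "mixture":
        roles = allocate_configurations(len(bases), config.percent_pairs, rng)
        roles = _assign_roles_feasibly(bases, roles, config, rng)
    else:
        roles = ["triplet"] * len(bases)
    flankers, demotions, fallbacks = place_flankers(
        bases, roles, config.arrangement, config, rng
    )
    discs = assign_polarity(list(bases) + flankers, config.polarity_scheme)
    return Display(
        discs=tuple(discs),
        arrangement=config.arrangement,
        mode=config.mode,
        percent_pairs=config.percent_pairs,
        polarity_scheme=config.polarity_scheme,
        base_count=len(bases),
        seed=config.seed,
        field=config.field_size,
        disc_radius=config.disc_radius,
        fixation_exclusion_radius=config.fixation_exclusion_radius,
        zone_major_factor=config.zone_major_factor,
        zone_minor_factor=config.zone_minor_factor,
        zones_within_field=config.zones_within_field,
        demotions=tuple(demotions),
        side_fallbacks=tuple(fallbacks),
    )


def _pack_exact(config: GeneratorConfig, base_count: int, max_tries: int = 200) -> list[Disc]:
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(max_tries):
        rng = np.random.default_rng(child)
        bases = pack_base_discs(config, rng)
        if len(bases) >= base_count:
            return bases[:base_count]
    raise RuntimeError(
        f"could not pack {base_count} bases in {max_tries} attempts; "
        "the field may be too small for that count"
    )


def validate_display(display: Display) -> list[str]:
    """Brute-force legality check; returns a list of violation messages."""
    problems: list[str] = []
    w, h = display.field
    r = display.disc_radius
    excl = display.fixation_exclusion_radius
    discs = display.discs
    by_id = {d.id: d for d in discs}

    for d in discs:
        if not _disc_fits_field(d.center.x, d.center.y, r, w, h, excl):
            problems.append(f"disc {d.id} violates field/exclusion constraints")
        if d.role == "flanker" and by_id.get(d.parent_id, d).role != "base":
            problems.append(f"flanker {d.id} has non-base parent {d.parent_id}")

    for i, a in enumerate(discs):
        for b in discs[i + 1 :]:
            if (
                math.hypot(a.center.x - b.center.x, a.center.y - b.center.y)
                < 2 * r - 1e-9
            ):
                problems.append(f"discs {a.id} and {b.id} overlap")

    bases = display.bases
    zone_pairs = {
        b.id: make_zones(b.center, display.zone_major_factor, display.zone_minor_factor)
        for b in bases
    }
    for i, a in enumerate(bases):
        for b in bases[i + 1 :]:
            for za in zone_pairs[a.id]:
                for zb in zone_pairs[b.id]:
                    if ellipses_overlap(za, zb):
                        problems.append(
                            f"zones of bases {a.id} and {b.id} overlap"
                        )
    if display.zones_within_field:
        for b in bases:
            zr, zt = zone_pairs[b.id]
            designated = zr if display.arrangement == "radial" else zt
            if not _zone_fits_field(designated, b.center.x, b.center.y, w, h, r):
                problems.append(
                    f"designated zone of base {b.id} leaves the inset field"
                )

    for f in display.flankers:
        parent = by_id[f.parent_id]
        zr, zt = zone_pairs[parent.id]
        designated, other = (zr, zt) if display.arrangement == "radial" else (zt, zr)
        if not point_in_ellipse(f.center, designated):
            problems.append(f"flanker {f.id} outside its designated zone")
        if in_zone_overlap(f.center, zr, zt):
            problems.append(f"flanker {f.id} inside the zone-overlap lens")
    return problems
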