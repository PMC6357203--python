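"""Synthetic semisolid-culture data at three fidelities, plus dye-dilution events.

The generator emulates the two-color mixing experiment: red- and green-labeled
platelets are seeded into viscous medium, incidental contacts during mixing
create "happen-to-be" doublets whose color composition is binomial
(r^2 : 2rg : g^2), and during culture a fraction of each color's platelets
divides, each division leaving a same-color doublet in place.

Three fidelities:

``expectation``
    Deterministic real-valued counts equal to the model expectations; the
    division-fraction estimator recovers the generating fractions exactly
    (algebraic fixed point).
``sampling``
    Counts with full sampling noise: the contact-pair color classes are
    multinomial, divisions are Bernoulli per platelet.  Divisions are
    restricted to non-contacted platelets so that every doublet is cleanly
    either a contact pair or a division pair and the estimator's model holds.
``spatial``
    Platelets are placed uniformly in microscopic fields; contacts emerge
    from actual proximity, division siblings are placed at a fixed offset,
    and clusters of three or more platelets are excluded from the counts
    (as visual counting excludes triplets and small clumps).  This mode can
    produce model violations (e.g. a division pair touching a bystander)
    and is the robustness testbed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .clustering import single_link_labels
from .counts import FieldCounts

__all__ = [
    "SimulationTruth",
    "ExpectedCounts",
    "SimulationResult",
    "simulate_counts",
    "render_fields",
    "simulate_dilution_events",
]


@dataclasses.dataclass(frozen=True)
class SimulationTruth:
    """Generative parameters of one synthetic experiment.

    ``n_contact_pairs`` (H) is the happen-to-be doublet budget in the count
    modes; in spatial mode contacts emerge from density instead and H is
    ignored.  Geometry is in micrometres, origin top-left, y downward.
    """

    r0: int
    g0: int
    n_contact_pairs: int = 0
    f_red: float = 0.0
    f_green: float = 0.0
    mode: str = "sampling"
    field_width: float = 100.0
    field_height: float = 100.0
    n_fields: int = 10
    contact_distance: float = 2.0
    division_offset: float = 1.0
    edge_margin: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("expectation", "sampling", "spatial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.r0 + self.g0 <= 0:
            raise ValueError("need at least one platelet")
        if self.r0 < 0 or self.g0 < 0:
            raise ValueError("platelet inputs must be non-negative")
        if 2 * self.n_contact_pairs > self.r0 + self.g0:
            raise ValueError(
                "infeasible contact budget: 2*n_contact_pairs exceeds platelet input"
            )
        if not (0.0 <= self.f_red <= 1.0 and 0.0 <= self.f_green <= 1.0):
            raise ValueError("division fractions must lie in [0, 1]")
        if self.division_offset >= self.contact_distance:
            raise ValueError("division_offset must be smaller than contact_distance")

    @property
    def expected_contacted(self) -> tuple[float, float]:
        """Expected platelets of each color consumed by contact pairs."""
        p = _contact_probs(self.r0, self.g0)
        h = self.n_contact_pairs
        return 2.0 * h * p[0] + h * p[1], 2.0 * h * p[2] + h * p[1]

    @property
    def implied_division_fractions(self) -> tuple[float, float]:
        """Model-implied true division fractions (newly generated / seeded).

        In expectation mode every platelet divides at its color's rate, so
        the division fraction equals ``f``.  In the stochastic count modes
        contacted platelets cannot divide (a dividing contacted platelet
        would form an excluded triplet), so the expected fraction of seeded
        platelets that divide is ``f * (1 - E[contacted]/n0)``.
        """
        if self.mode == "expectation":
            return self.f_red, self.f_green
        c_r, c_g = self.expected_contacted
        return (
            self.f_red * (self.r0 - c_r) / self.r0 if self.r0 else 0.0,
            self.f_green * (self.g0 - c_g) / self.g0 if self.g0 else 0.0,
        )

    @staticmethod
    def calibrate_division_probability(
        target_fraction: float, r0: int, g0: int, n_contact_pairs: int, color: str = "red"
    ) -> float:
        """Per-platelet division probability giving a true division fraction.

        Inverts ``implied_division_fractions`` so that a simulation can be
        parameterized directly by the division fraction it should realize.
        """
        p = _contact_probs(r0, g0)
        h = n_contact_pairs
        if color == "red":
            free = r0 - (2.0 * h * p[0] + h * p[1])
            n = r0
        else:
            free = g0 - (2.0 * h * p[2] + h * p[1])
            n = g0
        if free <= 0:
            raise ValueError("no platelets left free to divide")
        return target_fraction * n / free


@dataclasses.dataclass(frozen=True)
class ExpectedCounts:
    """Real-valued expectation-mode counts (duck-typed like FieldCounts)."""

    experiment_id: str
    condition: str
    n_red: float
    n_green: float
    d_rr: float
    d_gg: float
    d_rg: float

    def rounded(self) -> FieldCounts:
        return FieldCounts(
            self.experiment_id,
            self.condition,
            n_red=round(self.n_red),
            n_green=round(self.n_green),
            d_rr=round(self.d_rr),
            d_gg=round(self.d_gg),
            d_rg=round(self.d_rg),
        )


@dataclasses.dataclass(frozen=True)
class SimulationResult:
    counts: FieldCounts | ExpectedCounts
    truth: SimulationTruth
    n_divisions_red: int
    n_divisions_green: int
    ground_truth: pd.DataFrame | None = None  # spatial mode only
    n_excluded_platelets: int = 0
    n_multiplets: int = 0


def _contact_probs(r0: int, g0: int) -> np.ndarray:
    r = r0 / (r0 + g0)
    g = 1.0 - r
    return np.array([r * r, 2.0 * r * g, g * g])


def simulate_counts(truth: SimulationTruth) -> SimulationResult:
    """Generate one synthetic experiment at the fidelity set by ``truth.mode``."""
    if truth.mode == "expectation":
        return _simulate_expectation(truth)
    if truth.mode == "sampling":
        return _simulate_sampling(truth)
    return _simulate_spatial(truth)


def _simulate_expectation(truth: SimulationTruth) -> SimulationResult:
    h = truth.n_contact_pairs
    p = _contact_probs(truth.r0, truth.g0)
    counts = ExpectedCounts(
        experiment_id="sim-expectation",
        condition="cultured",
        n_red=truth.r0 * (1.0 + truth.f_red),
        n_green=truth.g0 * (1.0 + truth.f_green),
        d_rr=h * p[0] + truth.f_red * truth.r0,
        d_rg=h * p[1],
        d_gg=h * p[2] + truth.f_green * truth.g0,
    )
    return SimulationResult(
        counts=counts,
        truth=truth,
        n_divisions_red=0,
        n_divisions_green=0,
    )


def _draw_contact_classes(
    rng: np.random.Generator, h: int, r0: int, g0: int
) -> tuple[int, int, int]:
    """Multinomial contact classes, rejecting draws that overdraw a color."""
    p = _contact_probs(r0, g0)
    for _ in range(1000):
        h_rr, h_rg, h_gg = rng.multinomial(h, p)
        if 2 * h_rr + h_rg <= r0 and 2 * h_gg + h_rg <= g0:
            return int(h_rr), int(h_rg), int(h_gg)
    raise RuntimeError(
        "could not draw a feasible contact configuration; "
        "contact budget too large for the color totals"
    )


def _simulate_sampling(truth: SimulationTruth) -> SimulationResult:
    rng = np.random.default_rng(truth.seed)
    h_rr, h_rg, h_gg = _draw_contact_classes(
        rng, truth.n_contact_pairs, truth.r0, truth.g0
    )
    free_red = truth.r0 - 2 * h_rr - h_rg
    free_green = truth.g0 - 2 * h_gg - h_rg
    div_red = int(rng.binomial(free_red, truth.f_red)) if free_red > 0 else 0
    div_green = int(rng.binomial(free_green, truth.f_green)) if free_green > 0 else 0
    counts = FieldCounts(
        "sim-sampling",
        "cultured",
        n_red=truth.r0 + div_red,
        n_green=truth.g0 + div_green,
        d_rr=h_rr + div_red,
        d_gg=h_gg + div_green,
        d_rg=h_rg,
    )
    return SimulationResult(
        counts=counts,
        truth=truth,
        n_divisions_red=div_red,
        n_divisions_green=div_green,
    )


def _simulate_spatial(truth: SimulationTruth) -> SimulationResult:
    rng = np.random.default_rng(truth.seed)
    m = truth.edge_margin
    w, h = truth.field_width, truth.field_height
    if w - 2 * m <= 0 or h - 2 * m <= 0:
        raise ValueError("edge margin leaves no usable field area")

    n0 = truth.r0 + truth.g0
    channel = np.array(["red"] * truth.r0 + ["green"] * truth.g0)
    field = rng.integers(0, truth.n_fields, size=n0)
    x = rng.uniform(m, w - m, size=n0)
    y = rng.uniform(m, h - m, size=n0)
    f_prob = np.where(channel == "red", truth.f_red, truth.f_green)
    divides = rng.random(n0) < f_prob
    parent = np.arange(n0)

    # siblings placed at a fixed offset in a random direction
    idx = np.flatnonzero(divides)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
    sx = x[idx] + truth.division_offset * np.cos(theta)
    sy = y[idx] + truth.division_offset * np.sin(theta)
    sx = np.clip(sx, 0.0, w)
    sy = np.clip(sy, 0.0, h)

    df = pd.DataFrame(
        {
            "field": np.concatenate([field, field[idx]]),
            "x": np.concatenate([x, sx]),
            "y": np.concatenate([y, sy]),
            "channel": np.concatenate([channel, channel[idx]]),
            "parent": np.concatenate([parent, parent[idx]]),
            "is_progeny": np.concatenate(
                [np.zeros(n0, bool), np.ones(len(idx), bool)]
            ),
        }
    )
    df.index.name = "spot_id"

    labels = np.full(len(df), -1, dtype=int)
    offset = 0
    for f in range(truth.n_fields):
        sel = np.flatnonzero(df["field"].to_numpy() == f)
        if len(sel) == 0:
            continue
        lab = single_link_labels(df.iloc[sel][["x", "y"]].to_numpy(), truth.contact_distance)
        labels[sel] = lab + offset
        offset += lab.max() + 1 if len(lab) else 0
    df["cluster_id"] = labels

    sizes = df.groupby("cluster_id")["x"].transform("size").to_numpy()
    cls = np.where(
        sizes == 1, "singlet", np.where(sizes == 2, "doublet", "multiplet")
    ).astype(object)
    # subclassify doublets: siblings (same parent) vs happen-to-be contact
    for cid, grp in df[sizes == 2].groupby("cluster_id"):
        pair = grp.index.to_numpy()
        same_parent = df.loc[pair[0], "parent"] == df.loc[pair[1], "parent"]
        cls[pair] = "division_doublet" if same_parent else "htb_doublet"
    df["cluster_class"] = cls

    kept = df[df["cluster_class"] != "multiplet"]
    n_red = int((kept["channel"] == "red").sum())
    n_green = int((kept["channel"] == "green").sum())
    d_rr = d_gg = d_rg = 0
    for cid, grp in kept[kept["cluster_class"] != "singlet"].groupby("cluster_id"):
        chans = sorted(grp["channel"])
        if chans == ["red", "red"]:
            d_rr += 1
        elif chans == ["green", "green"]:
            d_gg += 1
        else:
            d_rg += 1
    counts = FieldCounts(
        "sim-spatial", "cultured", n_red=n_red, n_green=n_green,
        d_rr=d_rr, d_gg=d_gg, d_rg=d_rg,
    )
    n_multiplets = int(df.loc[df["cluster_class"] == "multiplet", "cluster_id"].nunique())
    return SimulationResult(
        counts=counts,
        truth=truth,
        n_divisions_red=int(divides[channel == "red"].sum()),
        n_divisions_green=int(divides[channel == "green"].sum()),
        ground_truth=df,
        n_excluded_platelets=int((df["cluster_class"] == "multiplet").sum()),
        n_multiplets=n_multiplets,
    )


def render_fields(
    ground_truth: pd.DataFrame,
    field_width: float,
    field_height: float,
    n_fields: int,
    psf_sigma: float = 0.3,
    pixel_size: float = 0.2,
    photon_scale: float = 20_000.0,
    background: float = 100.0,
    noise: str = "none",
    read_noise: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render ground-truth spots into a two-channel 16-bit image stack.

    Each spot becomes an isotropic Gaussian of integrated intensity
    ``photon_scale`` in its channel, on a constant ``background``.  A spot at
    (x, y) um lands at continuous pixel coordinate (x, y)/pixel_size, with
    pixel (i, j) centred at (i+0.5, j+0.5) — the same convention the spot
    detector uses to convert centroids back to micrometres.

    Returns a (n_fields, 2, ny, nx) uint16 array, channel 0 = red,
    channel 1 = green.
    """
    if noise not in ("none", "poisson_gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")
    if pixel_size > psf_sigma:
        raise ValueError("pixel_size must not exceed psf_sigma (undersampling)")
    import warnings

    rng = np.random.default_rng(seed)
    nx = int(round(field_width / pixel_size))
    ny = int(round(field_height / pixel_size))
    sigma_px = psf_sigma / pixel_size
    amp = photon_scale / (2.0 * np.pi * sigma_px**2)
    half = int(np.ceil(5.0 * sigma_px))
    stack = np.full((n_fields, 2, ny, nx), float(background))
    chan_index = {"red": 0, "green": 1}

    n_clipped = 0
    for _, spot in ground_truth.iterrows():
        f = int(spot["field"])
        if not 0 <= f < n_fields:
            continue
        u = spot["x"] / pixel_size
        v = spot["y"] / pixel_size
        if not (0.0 <= spot["x"] <= field_width and 0.0 <= spot["y"] <= field_height):
            n_clipped += 1
            continue
        c = chan_index[spot["channel"]]
        i0, i1 = int(np.floor(u)) - half, int(np.floor(u)) + half + 1
        j0, j1 = int(np.floor(v)) - half, int(np.floor(v)) + half + 1
        i0c, i1c = max(i0, 0), min(i1, nx)
        j0c, j1c = max(j0, 0), min(j1, ny)
        if i0c >= i1c or j0c >= j1c:
            n_clipped += 1
            continue
        ii = np.arange(i0c, i1c) + 0.5
        jj = np.arange(j0c, j1c) + 0.5
        gx = np.exp(-((ii - u) ** 2) / (2.0 * sigma_px**2))
        gy = np.exp(-((jj - v) ** 2) / (2.0 * sigma_px**2))
        stack[f, c, j0c:j1c, i0c:i1c] += amp * gy[:, None] * gx[None, :]
    if n_clipped:
        warnings.warn(
            f"{n_clipped} spot(s) outside the field were clipped",
            RuntimeWarning,
            stacklevel=2,
        )

    if noise == "poisson_gaussian":
        stack = rng.poisson(stack).astype(float)
        stack += rng.normal(0.0, read_noise, size=stack.shape)
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


def simulate_dilution_events(
    n_platelets: int,
    divided_fraction: float,
    gate_center: float = 3.0,
    gate_width: float = 0.05,
    intensity_cv: float = 0.05,
    leak_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic dye-dilution event list for a sorted, cultured population.

    Generation-0 intensities are lognormal truncated to the narrow sorting
    gate (``gate_center`` +/- ``gate_width``/2 in log10 units).  A platelet
    that divides is replaced by two events, each at half the parent
    intensity times lognormal multiplicative noise of coefficient of
    variation ``intensity_cv``.  ``leak_fraction`` of the undivided platelets
    are instead assigned intensities just below the gate, emulating sorter
    impurity (the nonzero "divided" percentages seen before culture).

    Returns a DataFrame with columns ``event_id``, ``intensity``,
    ``generation`` (0 = undivided, 1 = progeny of one division).
    """
    if not 0.0 <= divided_fraction <= 1.0:
        raise ValueError("divided_fraction must lie in [0, 1]")
    if not 0.0 <= leak_fraction <= 1.0:
        raise ValueError("leak_fraction must lie in [0, 1]")
    if gate_width <= 0.0:
        raise ValueError("gate_width must be positive")
    rng = np.random.default_rng(seed)

    # truncated normal in log10 via rejection; sd = gate_width so the gate
    # passes the bulk of a broad labeling distribution, as in sorting
    log10_i = rng.normal(gate_center, gate_width, size=4 * n_platelets)
    lo, hi = gate_center - gate_width / 2.0, gate_center + gate_width / 2.0
    log10_i = log10_i[(log10_i >= lo) & (log10_i <= hi)]
    while len(log10_i) < n_platelets:
        extra = rng.normal(gate_center, gate_width, size=4 * n_platelets)
        log10_i = np.concatenate([log10_i, extra[(extra >= lo) & (extra <= hi)]])
    parent_intensity = 10.0 ** log10_i[:n_platelets]

    divides = rng.random(n_platelets) < divided_fraction
    sigma_ln = np.sqrt(np.log1p(intensity_cv**2))

    undivided = parent_intensity[~divides]
    if leak_fraction > 0 and len(undivided):
        leaks = rng.random(len(undivided)) < leak_fraction
        # mis-sorted events land just below the gate
        undivided = undivided.copy()
        undivided[leaks] = 10.0 ** rng.uniform(
            lo - 0.45, lo - 0.05, size=int(leaks.sum())
        )
    n_div = int(divides.sum())
    children = np.repeat(parent_intensity[divides] / 2.0, 2)
    children *= np.exp(rng.normal(0.0, sigma_ln, size=2 * n_div))

    intensity = np.concatenate([undivided, children])
    generation = np.concatenate(
        [np.zeros(len(undivided), int), np.ones(2 * n_div, int)]
    )
    order = rng.permutation(len(intensity))
    return pd.DataFrame(
        {
            "event_id": np.arange(len(intensity)),
            "intensity": intensity[order],
            "generation": generation[order],
        }
    )
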