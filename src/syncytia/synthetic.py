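"""Synthetic-data generators with known ground truth for every assay.

Each generator emulates the statistical structure of one experimental
input — FRAP recoveries on a coupled cell graph, dual-dye mixing
images, bivariate cytometry clusters, logistic co-culture growth
plates, fluorescence histology slides, and log2 expression cohorts —
and returns a :class:`SyntheticTruth` holding the parameters needed to
predict the downstream analysis result without re-reading the data.
All generators are deterministic in their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import CellGeometry, CellGraph, ConcentrationState, simulate_network_diffusion
from .dye_exchange import DualChannelImage, EventTable
from .frap import FrapTrace
from .histology import Slide
from .rescue import GrowthPlate

__all__ = [
    "SyntheticTruth",
    "generate_cell_graph",
    "generate_frap_experiment",
    "generate_coculture_image",
    "generate_cytometry_events",
    "generate_growth_plate",
    "generate_histology_slide",
    "generate_expression_cohort",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted alongside every synthetic dataset."""

    scenario: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)


# ----------------------------------------------------------------- graphs

_HEX_DIRS = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]


def _hex_spiral(n: int) -> list[tuple[int, int]]:
    """First n axial coordinates of a hexagonal spiral around the origin."""
    coords = [(0, 0)]
    ring = 1
    while len(coords) < n:
        q, r = ring, 0
        # walk the six sides of the ring
        for dq, dr in [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]:
            for _ in range(ring):
                if len(coords) >= n:
                    return coords
                coords.append((q, r))
                q, r = q + dq, r + dr
        ring += 1
    return coords


def generate_cell_graph(
    n_cells: int,
    mean_area: float = 400.0,
    jitter: float = 0.1,
    seed: int = 0,
) -> tuple[CellGraph, SyntheticTruth]:
    """Confluent-monolayer stand-in: jittered hexagonal lattice of cells.

    Cells are regular hexagons of area ``mean_area * (1 + eps)`` with
    ``eps ~ Uniform(-jitter, jitter)``; neighbors on the lattice share a
    boundary equal to the shorter of their two hexagon side lengths, so
    each cell's contact total never exceeds its perimeter.  The graph is
    connected by construction.
    """
    if n_cells < 2:
        raise ValueError(f"need n_cells >= 2, got {n_cells}")
    if not (0 <= jitter < 1):
        raise ValueError("jitter must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    coords = _hex_spiral(n_cells)
    # regular hexagon: area = (3*sqrt(3)/2) * s^2, perimeter = 6 s
    areas = mean_area * (1 + rng.uniform(-jitter, jitter, size=n_cells))
    sides = np.sqrt(2 * areas / (3 * math.sqrt(3)))
    spacing = math.sqrt(2 * mean_area / (3 * math.sqrt(3))) * math.sqrt(3)
    cells = []
    index = {}
    for i, (q, r) in enumerate(coords):
        x = spacing * (q + r / 2)
        y = spacing * (math.sqrt(3) / 2) * r
        cells.append(
            CellGeometry(
                id=f"c{i}",
                area=float(areas[i]),
                perimeter=float(6 * sides[i]),
                centroid=(x, y),
            )
        )
        index[(q, r)] = i
    contacts = []
    for (q, r), i in index.items():
        for dq, dr in _HEX_DIRS:
            j = index.get((q + dq, r + dr))
            if j is not None and j > i:
                contacts.append((f"c{i}", f"c{j}", float(min(sides[i], sides[j]))))
    graph = CellGraph(cells=cells, contacts=contacts)
    truth = SyntheticTruth(
        scenario="cell_graph",
        seed=seed,
        params={"n_cells": n_cells, "mean_area": mean_area, "jitter": jitter},
    )
    return graph, truth


# ------------------------------------------------------------------- FRAP


def generate_frap_experiment(
    graph: CellGraph,
    P_true: float,
    bleach_cell: str,
    bleach_depth: float = 0.5,
    noise_sd: float = 0.0,
    sampling: float = 0.25,
    duration: float = 20.0,
    n_prebleach: int = 4,
    clamp_neighbors: bool = False,
    seed: int = 0,
) -> tuple[FrapTrace, SyntheticTruth]:
    """Simulated whole-cell FRAP recovery on a coupled monolayer.

    All cells start at the prebleach level 1; the bleached cell is set
    to ``bleach_depth`` (half-bleach by default, matching the imaging
    protocol) and the network-diffusion model generates the recovery at
    the true permeability.  ``clamp_neighbors`` holds every other cell
    at 1, realizing the infinite-reservoir geometry under which the
    monoexponential permeability estimator is exact.  Additive Gaussian
    noise of SD ``noise_sd`` is applied to the returned trace.
    """
    if not (0 < bleach_depth < 1):
        raise ValueError("bleach_depth must lie in (0, 1)")
    if P_true < 0:
        raise ValueError("P_true must be >= 0")
    try:
        idx = graph.index_of(bleach_cell)
    except KeyError:
        raise ValueError(f"bleach cell {bleach_cell!r} not in graph") from None
    rng = np.random.default_rng(seed)
    c0 = np.ones(len(graph))
    c0[idx] = bleach_depth
    clamped = (
        [c.id for c in graph.cells if c.id != bleach_cell] if clamp_neighbors else ()
    )
    states = simulate_network_diffusion(
        graph,
        ConcentrationState(time=0.0, concentrations=c0),
        permeability=P_true,
        duration=duration,
        step=sampling,
        clamped=clamped,
    )
    post_t = np.array([s.time for s in states])
    post_f = np.array([s.concentrations[idx] for s in states])
    pre_t = -sampling * np.arange(n_prebleach, 0, -1)
    times = np.concatenate([pre_t, post_t])
    signal = np.concatenate([np.ones(n_prebleach), post_f])
    if noise_sd > 0:
        signal = signal + rng.normal(0, noise_sd, size=signal.shape)
    trace = FrapTrace(times=times, signal=signal, bleach_index=n_prebleach)
    areas = graph.areas
    equilibrium = float(np.dot(areas, c0) / areas.sum())
    truth = SyntheticTruth(
        scenario="frap",
        seed=seed,
        params={
            "P_true": P_true,
            "bleach_cell": bleach_cell,
            "bleach_depth": bleach_depth,
            "noise_sd": noise_sd,
            "clamp_neighbors": clamp_neighbors,
            "equilibrium": 1.0 if clamp_neighbors else equilibrium,
        },
    )
    return trace, truth


# --------------------------------------------------------------- imaging


def _pack_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: int,
    max_tries: int = 20_000,
) -> list[tuple[int, int]]:
    """Random non-overlapping disk centers; raises after bounded retries."""
    centers: list[tuple[int, int]] = []
    min_d2 = (2 * radius + 1) ** 2
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not pack {n} disks of radius {radius} into {shape} "
                f"after {max_tries} tries"
            )
        tries += 1
        y = rng.integers(radius, shape[0] - radius)
        x = rng.integers(radius, shape[1] - radius)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d2 for cy, cx in centers):
            centers.append((int(y), int(x)))
    return centers


def generate_coculture_image(
    shape: tuple[int, int] = (512, 512),
    fraction_exchanged: float = 0.5,
    cell_radius_px: int = 12,
    n_cells: int = 120,
    noise_sd: float = 5.0,
    intensity: float = 1000.0,
    mixing_sd: float = 0.05,
    seed: int = 0,
) -> tuple[DualChannelImage, dict, SyntheticTruth]:
    """Dual-dye co-culture image with a planted exchanged fraction.

    Disk-shaped cells carry pure Orange, pure Violet, or — with
    probability ``fraction_exchanged`` — a mixture whose Orange share is
    drawn around 0.5 (SD ``mixing_sd``).  Background sits near zero with
    additive Gaussian noise.  Returns the image, a dict of auxiliary
    arrays (cell ``labels``, plus ``mono_O`` / ``mono_V`` single-dye
    control images used for normalization), and the truth record.
    """
    if not (0 <= fraction_exchanged <= 1):
        raise ValueError("fraction_exchanged must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    centers = _pack_disks(rng, shape, n_cells, cell_radius_px)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    labels = np.zeros(shape, dtype=int)
    chan_o = np.zeros(shape)
    chan_v = np.zeros(shape)
    mono_o = np.zeros(shape)
    mono_v = np.zeros(shape)
    kinds: list[str] = []
    mixes: list[float] = []
    for i, (cy, cx) in enumerate(centers, start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px**2
        labels[disk] = i
        exchanged = rng.random() < fraction_exchanged
        if exchanged:
            m = float(np.clip(rng.normal(0.5, mixing_sd), 0.05, 0.95))
            kinds.append("mixed")
        else:
            m = 1.0 if rng.random() < 0.5 else 0.0
            kinds.append("pure_O" if m == 1.0 else "pure_V")
        mixes.append(m)
        chan_o[disk] = intensity * m
        chan_v[disk] = intensity * (1 - m)
        mono_o[disk] = intensity
        mono_v[disk] = intensity
    if noise_sd > 0:
        for arr in (chan_o, chan_v, mono_o, mono_v):
            arr += rng.normal(0, noise_sd, size=shape)
            np.clip(arr, 0, None, out=arr)
    cell_mask = labels > 0
    img = DualChannelImage(
        channel_O=chan_o,
        channel_V=chan_v,
        mono_control_means=(
            float(mono_o[cell_mask].mean()),
            float(mono_v[cell_mask].mean()),
        ),
    )
    aux = {"labels": labels, "mono_O": mono_o, "mono_V": mono_v}
    truth = SyntheticTruth(
        scenario="coculture_image",
        seed=seed,
        params={
            "fraction_exchanged": fraction_exchanged,
            "n_cells": n_cells,
            "kinds": kinds,
            "mixing_fractions": mixes,
            "n_mixed": kinds.count("mixed"),
        },
    )
    return img, aux, truth


# -------------------------------------------------------------- cytometry


def generate_cytometry_events(
    n_per_population: int = 5000,
    exchanged_fraction: float = 0.5,
    channel_means: tuple[float, float] = (1e4, 1e4),
    channel_sds: tuple[float, float] = (0.35, 0.35),
    background_mean: float = 50.0,
    background_sd: float = 0.4,
    seed: int = 0,
) -> tuple[dict[str, EventTable], SyntheticTruth]:
    """Bivariate log-normal cytometry clusters with a planted dual fraction.

    The co-culture table holds ``n_per_population`` events of which
    ``exchanged_fraction`` are dual-positive (signal on both channels)
    and the rest split evenly between single-positive A and B.  Paired
    mono-culture tables (signal on one channel, background on the
    other) are emitted for percentile gating, and an acute-mix table
    (the two mono populations pooled, no exchange) as the null control.
    ``channel_sds`` and ``background_sd`` are log-scale SDs.
    """
    if n_per_population <= 0:
        raise ValueError("n_per_population must be > 0")
    if not (0 <= exchanged_fraction <= 1):
        raise ValueError("exchanged_fraction must lie in [0, 1]")
    if any(s <= 0 for s in channel_sds) or background_sd <= 0:
        raise ValueError("channel and background SDs must be > 0")
    rng = np.random.default_rng(seed)
    mu_a, mu_b = (math.log(m) for m in channel_means)
    s_a, s_b = channel_sds
    mu_bg = math.log(background_mean)

    def signal(n, mu, s):
        return np.exp(rng.normal(mu, s, size=n))

    def background(n):
        return np.exp(rng.normal(mu_bg, background_sd, size=n))

    n = n_per_population
    mono_a = EventTable(
        pd.DataFrame({"channel_A": signal(n, mu_a, s_a), "channel_B": background(n)}),
        source="mono_A",
    )
    mono_b = EventTable(
        pd.DataFrame({"channel_A": background(n), "channel_B": signal(n, mu_b, s_b)}),
        source="mono_B",
    )
    n_dual = int(round(exchanged_fraction * n))
    n_single = n - n_dual
    n_sa = n_single // 2
    n_sb = n_single - n_sa
    co = pd.DataFrame(
        {
            "channel_A": np.concatenate(
                [signal(n_dual, mu_a, s_a), signal(n_sa, mu_a, s_a), background(n_sb)]
            ),
            "channel_B": np.concatenate(
                [signal(n_dual, mu_b, s_b), background(n_sa), signal(n_sb, mu_b, s_b)]
            ),
        }
    )
    co = co.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(
        drop=True
    )
    co_table = EventTable(co, source="co_culture")
    acute = pd.DataFrame(
        {
            "channel_A": np.concatenate([signal(n_sa + n_dual // 2, mu_a, s_a), background(n - n_sa - n_dual // 2)]),
            "channel_B": np.concatenate([background(n_sa + n_dual // 2), signal(n - n_sa - n_dual // 2, mu_b, s_b)]),
        }
    )
    acute_table = EventTable(acute, source="acute_mix")
    truth = SyntheticTruth(
        scenario="cytometry",
        seed=seed,
        params={
            "exchanged_fraction": exchanged_fraction,
            "n_dual": n_dual,
            "n_per_population": n,
        },
    )
    return (
        {"mono_A": mono_a, "mono_B": mono_b, "co_culture": co_table, "acute_mix": acute_table},
        truth,
    )


# ------------------------------------------------------------ growth plate

DEFAULT_SEEDING_PAIRS = ((2000, 0), (1500, 500), (1000, 1000), (500, 1500), (0, 2000))


def _logistic_coculture(
    n_ko0: float,
    n_wt0: float,
    days: np.ndarray,
    r_ko: float,
    r_wt: float,
    capacity: float,
    rescue_strength: float,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-compartment logistic growth sharing one carrying capacity.

    The KO rate is inflated by ``rescue_strength`` times the current WT
    fraction, the simplest expression of a neighbor-supplied benefit.
    """
    t_end = float(days.max())
    n_steps = int(round(t_end / dt))
    ko = np.empty(n_steps + 1)
    wt = np.empty(n_steps + 1)
    ko[0], wt[0] = n_ko0, n_wt0
    for s in range(n_steps):
        total = ko[s] + wt[s]
        crowd = max(0.0, 1.0 - total / capacity)
        wt_frac = wt[s] / total if total > 0 else 0.0
        r_ko_eff = r_ko * (1.0 + rescue_strength * wt_frac)
        ko[s + 1] = ko[s] + dt * r_ko_eff * ko[s] * crowd
        wt[s + 1] = wt[s] + dt * r_wt * wt[s] * crowd
    idx = np.rint(days / dt).astype(int)
    return ko[idx], wt[idx]


def generate_growth_plate(
    seeding_pairs: Sequence[tuple[int, int]] = DEFAULT_SEEDING_PAIRS,
    days: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7),
    n_replicates: int = 5,
    r_wt: float = 0.7,
    r_ko: float = 0.7,
    capacity: float = 2e5,
    rescue_strength: float = 0.0,
    gfp_per_cell: float = 2.0,
    srb_per_cell: float = 1.0,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> tuple[GrowthPlate, SyntheticTruth]:
    """Co-culture growth plate with seeded KO:WT ratios over a week.

    Defaults follow the plate design of the rescue assays: seeding pairs
    (KO, WT) of 2000:0 through 0:2000 cells/well, daily readings to day
    7, five replicate wells.  GFP reads the KO compartment
    (``gfp_per_cell`` per cell) and SRB total biomass; both carry
    multiplicative Gaussian noise of CV ``noise_cv``.  Under the null
    (``rescue_strength = 0``, equal rates) measured GFP equals the
    seeding-scaled SRB expectation by construction.
    """
    if any(s < 0 for pair in seeding_pairs for s in pair):
        raise ValueError("seeding counts must be >= 0")
    if r_wt < 0 or r_ko < 0 or rescue_strength < 0:
        raise ValueError("growth rates and rescue_strength must be >= 0")
    rng = np.random.default_rng(seed)
    days_arr = np.asarray(sorted(days), dtype=float)
    rows = []
    for s_ko, s_wt in seeding_pairs:
        if s_ko + s_wt == 0:
            continue
        ko_t, wt_t = _logistic_coculture(
            s_ko, s_wt, days_arr, r_ko, r_wt, capacity, rescue_strength
        )
        if s_wt == 0:
            condition = "ko_mono"
        elif s_ko == 0:
            condition = "wt_mono"
        else:
            condition = "co"
        for rep in range(n_replicates):
            for d, n_ko, n_wt in zip(days_arr, ko_t, wt_t):
                gfp_clean = gfp_per_cell * n_ko
                srb_clean = srb_per_cell * (n_ko + n_wt)
                gfp = gfp_clean * (1 + rng.normal(0, noise_cv)) if gfp_clean > 0 else abs(
                    rng.normal(0, noise_cv * srb_clean * 0.01)
                )
                srb = srb_clean * (1 + rng.normal(0, noise_cv))
                rows.append(
                    {
                        "well_id": f"ko{s_ko}_wt{s_wt}_r{rep}",
                        "day": int(d),
                        "seeding_ko": s_ko,
                        "seeding_wt": s_wt,
                        "gfp": gfp,
                        "srb": srb,
                        "condition": condition,
                    }
                )
    plate = GrowthPlate(pd.DataFrame(rows))
    truth = SyntheticTruth(
        scenario="growth_plate",
        seed=seed,
        params={
            "rescue_strength": rescue_strength,
            "r_wt": r_wt,
            "r_ko": r_ko,
            "gfp_per_cell": gfp_per_cell,
            "srb_per_cell": srb_per_cell,
            "calibration_slope": gfp_per_cell / srb_per_cell,
            "noise_cv": noise_cv,
            "seeding_pairs": list(map(tuple, seeding_pairs)),
        },
    )
    return plate, truth


# -------------------------------------------------------------- histology


def _rect_blob(area: int) -> np.ndarray:
    """Boolean blob of exactly ``area`` pixels (rectangle + partial row)."""
    side = max(1, int(math.isqrt(area)))
    rows = area // side
    rem = area - rows * side
    h = rows + (1 if rem else 0)
    blob = np.zeros((h, side), dtype=bool)
    blob[:rows, :] = True
    if rem:
        blob[rows, :rem] = True
    return blob


def generate_histology_slide(
    shape: tuple[int, int] = (1024, 1024),
    tumor_axes: tuple[int, int] = (440, 350),
    n_clusters: int = 12,
    cluster_area_px: int = 400,
    background_mean: float = 500.0,
    background_sd: float = 20.0,
    cluster_height_sd: float = 12.0,
    nuclear_spacing_px: int = 5,
    noise_clip_sd: float = 4.0,
    slide_index: int = 0,
    seed: int = 0,
) -> tuple[Slide, SyntheticTruth]:
    """Tumor section with GFP clusters of known count and exact pixel area.

    The tumor is an ellipse; the nuclear channel carries dense nuclei
    (one per ``nuclear_spacing_px`` grid point inside the tumor) so a
    small dilation fuses them into the tumor mask.  The GFP channel is
    Gaussian background (truncated at ``noise_clip_sd`` SDs, so no
    stray background pixel can cross a k <= 6 threshold) inside the
    tumor plus ``n_clusters`` uniform blobs of exactly
    ``cluster_area_px`` pixels at ``cluster_height_sd`` background SDs
    above the mean — bright enough to survive thresholding at k = 4, 5
    and 6 even after the clusters themselves inflate the measured SD.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = h // 2, w // 2
    ay, ax = tumor_axes
    if 2 * ay >= h or 2 * ax >= w:
        raise ValueError("tumor axes do not fit inside the image")
    yy, xx = np.mgrid[:h, :w]
    tumor = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    # nuclei: jittered grid of 2-px-radius spots covering the tumor
    nuclear = np.zeros(shape)
    step = nuclear_spacing_px
    gy, gx = np.mgrid[step // 2 : h : step, step // 2 : w : step]
    jit = rng.integers(-1, 2, size=(2,) + gy.shape)
    py = np.clip(gy + jit[0], 1, h - 2)
    px = np.clip(gx + jit[1], 1, w - 2)
    inside = tumor[py, px]
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            nuclear[py[inside] + dy, px[inside] + dx] = 1000.0
    nuclear += np.abs(rng.normal(0, 10.0, size=shape))

    # diffuse staining background covers the whole section, not just tumor
    noise = rng.normal(0, background_sd, size=shape)
    np.clip(noise, -noise_clip_sd * background_sd, noise_clip_sd * background_sd, out=noise)
    gfp = background_mean + noise

    blob = _rect_blob(cluster_area_px)
    bh, bw = blob.shape
    margin = max(bh, bw) + 4
    centers: list[tuple[int, int]] = []
    occupied = np.zeros(shape, dtype=bool)
    tries = 0
    cluster_value = background_mean + cluster_height_sd * background_sd
    while len(centers) < n_clusters:
        if tries > 20_000:
            raise RuntimeError(
                f"could not place {n_clusters} clusters of {cluster_area_px} px "
                "inside the tumor region"
            )
        tries += 1
        y = int(rng.integers(margin, h - margin))
        x = int(rng.integers(margin, w - margin))
        # whole blob plus a 2-px separation ring must sit inside the tumor
        win_t = tumor[y - 2 : y + bh + 2, x - 2 : x + bw + 2]
        win_o = occupied[y - 2 : y + bh + 2, x - 2 : x + bw + 2]
        if win_t.all() and not win_o.any():
            gfp[y : y + bh, x : x + bw][blob] = cluster_value
            occupied[y - 2 : y + bh + 2, x - 2 : x + bw + 2] = True
            centers.append((y, x))
    slide = Slide(nuclear=nuclear, gfp=gfp, slide_index=slide_index)
    truth = SyntheticTruth(
        scenario="histology_slide",
        seed=seed,
        params={
            "n_clusters": n_clusters,
            "cluster_area_px": cluster_area_px,
            "ensemble_area_px": n_clusters * cluster_area_px,
            "tumor_area_px": int(tumor.sum()),
            "background_mean": background_mean,
            "background_sd": background_sd,
            "cluster_centers": centers,
        },
    )
    return slide, truth


# ------------------------------------------------------------- expression


def generate_expression_cohort(
    n_lines: int = 79,
    mode: str = "bimodal",
    means: tuple[float, float] = (3.0, 8.0),
    sds: tuple[float, float] = (0.5, 0.5),
    mixing: float = 0.5,
    gene: str = "GENE",
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Log2 expression values for a cell-line cohort (default n = 79).

    ``mode='unimodal'`` draws from one Gaussian (the first mean/SD);
    ``mode='bimodal'`` from a two-component mixture with the given
    mixing weight.  A degenerate request (equal means under bimodal)
    is generated as asked but flagged in the truth record.
    """
    if mode not in ("unimodal", "bimodal"):
        raise ValueError("mode must be 'unimodal' or 'bimodal'")
    if mode == "bimodal" and n_lines < 20:
        raise ValueError("bimodal mode needs n_lines >= 20")
    rng = np.random.default_rng(seed)
    degenerate = mode == "bimodal" and means[0] == means[1]
    if mode == "unimodal":
        values = rng.normal(means[0], sds[0], size=n_lines)
    else:
        comp = rng.random(n_lines) < mixing
        values = np.where(
            comp,
            rng.normal(means[0], sds[0], size=n_lines),
            rng.normal(means[1], sds[1], size=n_lines),
        )
    truth = SyntheticTruth(
        scenario="expression_cohort",
        seed=seed,
        params={
            "mode": mode,
            "means": list(means),
            "sds": list(sds),
            "mixing": mixing,
            "gene": gene,
            "degenerate": degenerate,
        },
    )
    return values, truth
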