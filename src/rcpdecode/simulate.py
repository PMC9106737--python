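"""Synthetic in situ sequencing experiments with full ground truth.

The generator emulates the signal structure the pipeline assumes: cells are
disks (a nucleus disk inside a larger cytoplasm disk), rolling-circle
products (RCPs) are isotropic Gaussian spots of a fixed amplitude drawn
Poisson-distributed per cell and gene, rendered into the channel(s) dictated
by the codebook — at the same stitched position in every cycle for
combinatorial readout.  The stitched canvas is then cut into overlapping
tiles (optionally translated by an integer stage jitter), expanded into
z-stacks whose in-focus plane carries the signal, and degraded with a
constant background plus additive Gaussian noise.  With this noise model the
per-spot signal-to-noise ratio is analytically ``spot_amplitude /
gaussian_noise_sd``.

Everything is reproducible: the same :class:`SimulationConfig` yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simio import AcquisitionLayout, Codebook, TileSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "paired_condition_fixture",
    "planted_expression_matrix",
    "default_codebook",
    "simulation_config_from_yaml",
    "write_ground_truth",
]

_U16MAX = np.float64(np.iinfo(np.uint16).max)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Rates are per cell and per gene (``spots_per_cell_per_gene`` is the
    Poisson mean, multiplied globally by ``efficiency_scale`` — the knob used
    to emulate chemistries with different detection efficiencies).  Lengths
    are in pixels of the stitched canvas.  ``min_spot_separation_px`` > 0
    enforces a minimum distance between rendered RCPs (rejection sampling),
    for fixtures that require resolvable spots.
    """

    layout: AcquisitionLayout = field(default_factory=AcquisitionLayout)
    n_cells: int = 30
    nucleus_radius_px: tuple[float, float] = (7.0, 1.0)  # mean, sd
    cell_radius_px: float = 20.0
    spots_per_cell_per_gene: float = 2.5
    psf_sigma_px: float = 1.2  # ~1 um RCP at a 20X/0.32 um-per-px scale
    spot_amplitude: float = 20000.0
    nucleus_amplitude: float = 30000.0
    background_level: float = 3000.0
    gaussian_noise_sd: float = 1000.0
    crosstalk_fraction: float = 0.0
    tile_offset_jitter_px: int = 0
    efficiency_scale: float = 1.0
    gene_rate_factors: tuple[float, ...] | None = None  # per-gene abundance
    cell_expression_sigma: float = 0.0  # sd of per-cell log-normal scale
    min_spot_separation_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spots_per_cell_per_gene < 0 or self.efficiency_scale <= 0:
            raise ValueError("spot rates must be >= 0 and efficiency_scale > 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if not (0.0 <= self.crosstalk_fraction < 0.5):
            raise ValueError("crosstalk_fraction must lie in [0, 0.5)")
        if self.tile_offset_jitter_px < 0:
            raise ValueError("tile_offset_jitter_px must be >= 0")
        if self.cell_radius_px < self.nucleus_radius_px[0]:
            raise ValueError("cell_radius_px must be >= mean nucleus radius")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    spots: pd.DataFrame  # gene, y, x, cell_id (stitched coordinates)
    cells: pd.DataFrame  # cell_id, y, x, nucleus_radius_px
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    tile_offsets: pd.DataFrame  # tile, nominal_y, nominal_x, true_y, true_x
    counts: pd.DataFrame  # cells x genes table of true per-cell counts
    clean_canvases: dict[tuple[int, int], np.ndarray]  # noise-free signal+bg


# ---------------------------------------------------------------------------
# geometry


def _place_cells(rng: np.random.Generator, config: SimulationConfig,
                 shape: tuple[int, int]) -> pd.DataFrame:
    """Place nuclei without overlap (rejection sampling, bounded attempts)."""
    h, w = shape
    mu, sd = config.nucleus_radius_px
    margin = config.cell_radius_px
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("canvas too small for the configured cell radius")
    min_sep = 2.0 * (mu + 2.0 * max(sd, 0.0)) + 4.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts_per_cell = 200
    for _ in range(config.n_cells):
        for attempt in range(attempts_per_cell):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
                centers.append((y, x))
                radii.append(max(2.0, rng.normal(mu, sd)))
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping nuclei; "
                "reduce n_cells or enlarge the grid"
            )
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, len(centers) + 1, dtype=np.int64),
            "y": [c[0] for c in centers],
            "x": [c[1] for c in centers],
            "nucleus_radius_px": radii,
        }
    )


def _truth_masks(cells: pd.DataFrame, config: SimulationConfig,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus disks and nearest-center cytoplasm territories (disk-capped)."""
    h, w = shape
    nucleus = np.zeros(shape, dtype=np.int64)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    centers = cells[["y", "x"]].to_numpy()
    if len(centers) == 0:
        return nucleus, nucleus.copy()
    dist, idx = cKDTree(centers).query(pts, k=1)
    dist = dist.reshape(shape)
    idx = idx.reshape(shape)
    cell_mask = np.where(dist <= config.cell_radius_px,
                         cells["cell_id"].to_numpy()[idx], 0)
    radii = cells["nucleus_radius_px"].to_numpy()[idx]
    nucleus = np.where(dist <= radii, cells["cell_id"].to_numpy()[idx], 0)
    return nucleus.astype(np.int64), cell_mask.astype(np.int64)


def _draw_spots(rng: np.random.Generator, cells: pd.DataFrame,
                config: SimulationConfig, genes: list[str],
                shape: tuple[int, int]) -> pd.DataFrame:
    """Poisson spot positions per cell x gene, inside the cytoplasm disk."""
    h, w = shape
    base = config.spots_per_cell_per_gene * config.efficiency_scale
    factors = config.gene_rate_factors or (1.0,) * len(genes)
    if len(factors) != len(genes):
        raise ValueError("gene_rate_factors must have one entry per gene")
    rows: list[tuple[str, float, float, int]] = []
    placed: list[tuple[float, float]] = []
    sep2 = config.min_spot_separation_px**2
    for _, cell in cells.iterrows():
        for gene, factor in zip(genes, factors):
            n = rng.poisson(base * factor * cell["expression_scale"])
            for _ in range(n):
                for attempt in range(100):
                    r = config.cell_radius_px * np.sqrt(rng.uniform())
                    theta = rng.uniform(0, 2 * np.pi)
                    y = cell["y"] + r * np.sin(theta)
                    x = cell["x"] + r * np.cos(theta)
                    if not (0 <= y < h and 0 <= x < w):
                        continue
                    if sep2 > 0 and any(
                        (y - py) ** 2 + (x - px) ** 2 < sep2 for py, px in placed
                    ):
                        continue
                    rows.append((gene, y, x, int(cell["cell_id"])))
                    if sep2 > 0:
                        placed.append((y, x))
                    break
                # an unplaceable spot is dropped; ground truth stays consistent
    return pd.DataFrame(rows, columns=["gene", "y", "x", "cell_id"]).astype(
        {"cell_id": np.int64}
    )


# ---------------------------------------------------------------------------
# rendering


def _render_gaussian(canvas: np.ndarray, y: float, x: float,
                     amplitude: float, sigma: float) -> None:
    h, w = canvas.shape
    half = int(np.ceil(4 * sigma))
    yi, xi = int(round(y)), int(round(x))
    y0, y1 = max(0, yi - half), min(h, yi + half + 1)
    x0, x1 = max(0, xi - half), min(w, xi + half + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2)
    )


def _render_canvases(spots: pd.DataFrame, cells: pd.DataFrame,
                     config: SimulationConfig, codebook: Codebook,
                     shape: tuple[int, int]) -> dict[tuple[int, int], np.ndarray]:
    layout = config.layout
    canvases = {
        (r, c): np.zeros(shape, dtype=np.float64)
        for r in range(layout.n_rounds)
        for c in range(layout.n_channels)
    }
    # nuclei appear in the nuclear channel of every round
    nuc_sigma = 1.0
    for r in range(layout.n_rounds):
        dapi = canvases[(r, layout.nuclear_channel)]
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for _, cell in cells.iterrows():
            rad = cell["nucleus_radius_px"]
            yi, xi = cell["y"], cell["x"]
            half = int(np.ceil(rad + 4))
            y0, y1 = max(0, int(yi - half)), min(shape[0], int(yi + half + 1))
            x0, x1 = max(0, int(xi - half)), min(shape[1], int(xi + half + 1))
            d = np.sqrt((yy[y0:y1, x0:x1] - yi) ** 2 + (xx[y0:y1, x0:x1] - xi) ** 2)
            # soft-edged disk: full amplitude inside, Gaussian falloff at rim
            profile = np.where(
                d <= rad, 1.0, np.exp(-((d - rad) ** 2) / (2 * nuc_sigma**2))
            )
            dapi[y0:y1, x0:x1] += config.nucleus_amplitude * profile
    # RCPs per codebook
    for _, s in spots.iterrows():
        assignment = codebook.entries[s["gene"]]
        if codebook.mode == "sequential":
            targets = [assignment]  # one (round, channel)
        else:
            targets = list(enumerate(assignment))  # cycle i -> channel
        for rnd, ch in targets:
            _render_gaussian(
                canvases[(rnd, ch)], s["y"], s["x"],
                config.spot_amplitude, config.psf_sigma_px,
            )
    # channel crosstalk among signal channels, per round
    if config.crosstalk_fraction > 0:
        xf = config.crosstalk_fraction
        for r in range(layout.n_rounds):
            sig = [canvases[(r, c)].copy() for c in layout.signal_channels]
            total = np.sum(sig, axis=0)
            for i, c in enumerate(layout.signal_channels):
                canvases[(r, c)] = sig[i] + xf * (total - sig[i])
    return canvases


def _cut_tiles(canvases: dict[tuple[int, int], np.ndarray],
               config: SimulationConfig,
               rng: np.random.Generator) -> tuple[dict, pd.DataFrame]:
    layout = config.layout
    h, w = layout.canvas_shape
    th, tw = layout.tile_height_px, layout.tile_width_px
    jmax = config.tile_offset_jitter_px
    offsets = []
    stacks: dict[tuple[int, int, int], np.ndarray] = {}
    focus = layout.z_steps // 2
    for t in range(layout.n_tiles):
        oy, ox = layout.nominal_offset(t)
        jy = int(rng.integers(-jmax, jmax + 1)) if jmax else 0
        jx = int(rng.integers(-jmax, jmax + 1)) if jmax else 0
        ty = int(np.clip(oy + jy, 0, h - th))
        tx = int(np.clip(ox + jx, 0, w - tw))
        offsets.append((t, oy, ox, ty, tx))
        for r in range(layout.n_rounds):
            for c in range(layout.n_channels):
                window = canvases[(r, c)][ty : ty + th, tx : tx + tw]
                stack = np.empty((layout.z_steps, th, tw), dtype=np.float64)
                for z in range(layout.z_steps):
                    plane = window if z == focus else 0.0
                    stack[z] = plane + config.background_level
                    if config.gaussian_noise_sd > 0:
                        stack[z] += rng.normal(
                            0.0, config.gaussian_noise_sd, size=(th, tw)
                        )
                stacks[(t, r, c)] = np.clip(stack, 0, _U16MAX).astype(np.uint16)
    off = pd.DataFrame(
        offsets, columns=["tile", "nominal_y", "nominal_x", "true_y", "true_x"]
    )
    return stacks, off


def _count_table(spots: pd.DataFrame, cells: pd.DataFrame,
                 genes: list[str]) -> pd.DataFrame:
    counts = pd.DataFrame(
        0, index=cells["cell_id"].to_numpy(), columns=genes, dtype=np.int64
    )
    if len(spots):
        tally = spots.groupby(["cell_id", "gene"]).size()
        for (cid, gene), n in tally.items():
            counts.loc[cid, gene] = n
    counts.index.name = "cell_id"
    return counts


def simulate_experiment(config: SimulationConfig,
                        codebook: Codebook) -> tuple[TileSet, GroundTruth]:
    """Generate one synthetic experiment and its full ground truth.

    Nuclei are placed without overlap; per cell and gene a Poisson number of
    RCPs is drawn within the cytoplasm disk; each RCP is rendered into the
    channel(s) the codebook dictates (same stitched position every cycle in
    combinatorial mode); the canvas is cut into overlapping tiles with an
    optional integer stage jitter, stacked in z, and degraded with background
    plus Gaussian noise.
    """
    codebook.validate_against(config.layout)
    rng = np.random.default_rng(config.seed)
    shape = config.layout.canvas_shape
    cells = _place_cells(rng, config, shape)
    # per-cell expression scale (cell-type heterogeneity); drawn before any
    # spot so paired conditions share it along with the geometry
    if config.cell_expression_sigma > 0:
        cells["expression_scale"] = rng.lognormal(
            0.0, config.cell_expression_sigma, len(cells)
        )
    else:
        cells["expression_scale"] = 1.0
    spots = _draw_spots(rng, cells, config, codebook.genes, shape)
    nucleus_mask, cell_mask = _truth_masks(cells, config, shape)
    signal = _render_canvases(spots, cells, config, codebook, shape)
    clean = {
        key: np.clip(img + config.background_level, 0, _U16MAX).astype(np.uint16)
        for key, img in signal.items()
    }
    stacks, offsets = _cut_tiles(signal, config, rng)
    gt = GroundTruth(
        spots=spots,
        cells=cells,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        tile_offsets=offsets,
        counts=_count_table(spots, cells, codebook.genes),
        clean_canvases=clean,
    )
    return TileSet(layout=config.layout, stacks=stacks), gt


def paired_condition_fixture(
    config: SimulationConfig, codebook: Codebook, ratio: float
) -> tuple[tuple[TileSet, GroundTruth], tuple[TileSet, GroundTruth]]:
    """Two experiments sharing cell geometry, the second with all spot rates
    multiplied by ``ratio``.

    Both runs use the same seed, so nucleus placement (drawn before any spot)
    is identical; only the expected RCP rate differs — the ground-truth
    per-gene rate ratio is exactly ``ratio``.  This is the machine twin of a
    chemistry comparison in consecutive tissue sections.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    low = simulate_experiment(config, codebook)
    high = simulate_experiment(
        replace(config, efficiency_scale=config.efficiency_scale * ratio), codebook
    )
    return low, high


# ---------------------------------------------------------------------------
# planted expression mixtures (for clustering tests)


def planted_expression_matrix(
    n_pops: int,
    cells_per_pop: int,
    markers_per_pop: int = 4,
    marker_rate: float = 10.0,
    background_rate: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Poisson count matrix with ``n_pops`` populations, each expressing a
    disjoint block of marker genes at ``marker_rate`` over a flat
    ``background_rate``.  Returns (counts, population labels, gene names).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_pops * markers_per_pop
    n_cells = n_pops * cells_per_pop
    labels = np.repeat(np.arange(n_pops), cells_per_pop)
    rates = np.full((n_cells, n_genes), background_rate)
    for p in range(n_pops):
        rows = labels == p
        cols = slice(p * markers_per_pop, (p + 1) * markers_per_pop)
        rates[rows, cols] = marker_rate
    counts = rng.poisson(rates).astype(np.int64)
    genes = [f"gene{g:02d}" for g in range(n_genes)]
    perm = rng.permutation(n_cells)  # shuffle so order carries no signal
    return counts[perm], labels[perm], genes


def simulation_config_from_yaml(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML (``layout`` is a nested
    mapping; unknown keys anywhere are rejected)."""
    import dataclasses
    from pathlib import Path

    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError("unknown simulation keys: " + ", ".join(map(repr, unknown)))
    if "layout" in doc:
        doc["layout"] = AcquisitionLayout.from_dict(doc["layout"])
    if "nucleus_radius_px" in doc:
        doc["nucleus_radius_px"] = tuple(doc["nucleus_radius_px"])
    return SimulationConfig(**doc)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write a :class:`GroundTruth` as CSV tables plus label-mask TIFFs."""
    from pathlib import Path

    from .simio import write_label_mask

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gt.spots.to_csv(path / "true_spots.csv", index=False)
    gt.cells.to_csv(path / "true_cells.csv", index=False)
    gt.tile_offsets.to_csv(path / "true_tile_offsets.csv", index=False)
    gt.counts.to_csv(path / "true_counts.csv")
    write_label_mask(gt.nucleus_mask, path / "true_nucleus_mask.tif")
    write_label_mask(gt.cell_mask, path / "true_cell_mask.tif")


def default_codebook(layout: AcquisitionLayout, n_genes: int = 4,
                     mode: str = "sequential", n_cycles: int = 2) -> Codebook:
    """Convenience codebook over a layout's signal channels.

    Sequential: genes fill (round, channel) slots in round-major order.
    Combinatorial: the first ``n_genes`` distinct channel sequences of length
    ``n_cycles`` in lexicographic order.
    """
    sig = layout.signal_channels
    if mode == "sequential":
        slots = [(r, c) for r in range(layout.n_rounds) for c in sig]
        if n_genes > len(slots):
            raise ValueError("not enough (round, channel) slots for n_genes")
        entries = {f"gene{i:02d}": slots[i] for i in range(n_genes)}
    else:
        from itertools import product

        codes = [code for code in product(sig, repeat=n_cycles)
                 if len(set(code)) > 1]  # avoid flat codes: harder to confuse
        if n_genes > len(codes):
            raise ValueError("not enough channel sequences for n_genes")
        entries = {f"gene{i:02d}": codes[i] for i in range(n_genes)}
    return Codebook(mode=mode, entries=entries)
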