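"""Synthetic mosaic cultures: stochastic growth, mitotic recombination,
spring-relaxed layout, and dosage-conditioned fluorescence.

A culture grows from a single heterozygous (dosage 1) cell through
synchronous rounds of stochastic division.  While a recombination window is
open — starting when the population first reaches ``recombination_start_size``
and lasting ``recombination_duration`` generations — each dividing dosage-1
parent may undergo mitotic recombination, partitioning its two marker-gene
copies unequally so one daughter receives both (dosage 2) and the other none
(dosage 0).  Dosage-0 and dosage-2 lineages are genetically sealed.  The two
window parameters tune the number and size of the resulting clones: earlier
onsets produce fewer, larger clones.

After every division round the cells are repositioned by relaxing a spring
network over the Delaunay triangulation (hull slivers removed by a
maximum-angle rule).  Springs between same-dosage neighbors are 10% stiffer,
which keeps clonal siblings spatially cohesive while preserving an
approximately uniform density.

Fluorescence is sampled per cell from a lognormal conditioned on dosage n:
ln x ~ N(mu_n, sigma_alpha^2) with mu_n = ln 2^(n-1), so the mean level
doubles per gene copy; sigma_alpha (the fluorescence ambiguity) controls
how much adjacent dosage distributions overlap.  Cultures can be rendered
as synthetic multichannel images (uniform-intensity nuclear-stain disks plus
marker disks shaded by sampled level) to exercise the segmentation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .data import MeasurementTable
from .errors import ParameterError

REST_LENGTH_DEFAULT = 1.0
SPRING_ITERATIONS = 50
SPRING_STEP = 0.2
SAME_DOSAGE_STIFFNESS = 1.1
MAX_SLIVER_ANGLE_DEG = 150.0


@dataclass
class GrowthParams:
    """Growth / recombination parameters (benchmark defaults)."""

    division_prob: float = 0.2            # per-cell division probability per round
    recombination_prob: float = 0.2       # per-division recombination probability
    recombination_start_size: int = 16    # population at which the window opens
    recombination_duration: int = 4       # window length in generations
    final_size: int = 2048                # stop once the population exceeds this

    def validate(self):
        if not (0 < self.division_prob <= 1):
            raise ParameterError("division_prob must lie in (0, 1]")
        if not (0 <= self.recombination_prob <= 1):
            raise ParameterError("recombination_prob must lie in [0, 1]")
        if self.final_size < 2:
            raise ParameterError("final_size must be >= 2")
        if self.recombination_start_size < 1 or self.recombination_duration < 0:
            raise ParameterError("invalid recombination window")


@dataclass
class FluorescenceParams:
    """Dosage-conditioned lognormal fluorescence parameters.

    mu_n = ln 2^(n-1) exactly (-ln2, 0, ln2 for n = 0, 1, 2), so the mean
    level doubles per additional gene copy; ``sigma_alpha`` is the log-scale
    standard deviation (fluorescence ambiguity).
    """

    sigma_alpha: float = 0.25

    def __post_init__(self):
        if self.sigma_alpha <= 0:
            raise ParameterError("sigma_alpha must be positive")

    @staticmethod
    def mu(dosage) -> np.ndarray:
        return (np.asarray(dosage, dtype=float) - 1.0) * np.log(2.0)


@dataclass
class SyntheticCulture:
    """Full lineage record of one simulated culture.

    Arrays run over every cell ever created; ``alive`` marks the final
    population.  ``clone_id`` is inherited through ordinary divisions and
    freshly allocated for both daughters of a recombination event, so clones
    are exactly the maximal constant-dosage lineage subtrees (clone 0 being
    the residual dosage-1 population).
    """

    ids: np.ndarray
    parents: np.ndarray            # -1 for the seed cell
    dosages: np.ndarray
    born: np.ndarray               # generation of birth
    clone_ids: np.ndarray
    positions: np.ndarray          # (n_cells_ever, 2), last known position
    alive: np.ndarray              # boolean
    params: GrowthParams
    seed: int | None
    n_generations: int
    n_recombinations: int
    meta: dict = field(default_factory=dict)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def alive_positions(self) -> np.ndarray:
        return self.positions[self.alive]

    @property
    def alive_dosages(self) -> np.ndarray:
        return self.dosages[self.alive]

    @property
    def alive_clone_ids(self) -> np.ndarray:
        return self.clone_ids[self.alive]


def grow_culture(params: GrowthParams | None = None, seed: int | None = None) -> SyntheticCulture:
    """Grow a culture from a single dosage-1 seed cell.

    Synchronous rounds of {division, recombination, repositioning} repeat
    until the population exceeds ``params.final_size``.  At every division
    the daughters' dosages sum to twice the parent's.  All randomness flows
    from ``seed``; identical seeds give identical cultures.
    """
    if params is None:
        params = GrowthParams()
    params.validate()
    rng = np.random.default_rng(seed)

    ids = [0]
    parents = [-1]
    dosages = [1]
    born = [0]
    clone_ids = [0]
    positions = [np.zeros(2)]
    alive = [True]
    alive_idx = [0]

    next_clone = 1
    n_recomb = 0
    onset: int | None = None
    gen = 0
    spacing = REST_LENGTH_DEFAULT

    while len(alive_idx) <= params.final_size:
        gen += 1
        if onset is None and len(alive_idx) >= params.recombination_start_size:
            onset = gen
        window_open = onset is not None and gen < onset + params.recombination_duration

        new_alive: list[int] = []
        divides = rng.random(len(alive_idx)) < params.division_prob
        recomb_draws = rng.random(len(alive_idx))
        angles = rng.uniform(0, 2 * np.pi, len(alive_idx))
        for j, i in enumerate(alive_idx):
            if not divides[j]:
                new_alive.append(i)
                continue
            recombines = (
                window_open
                and dosages[i] == 1
                and recomb_draws[j] < params.recombination_prob
            )
            if recombines:
                child_dosages = (2, 0)
                child_clones = (next_clone, next_clone + 1)
                next_clone += 2
                n_recomb += 1
            else:
                child_dosages = (dosages[i], dosages[i])
                child_clones = (clone_ids[i], clone_ids[i])
            offset = 0.25 * spacing * np.array([np.cos(angles[j]), np.sin(angles[j])])
            for sgn, cd, cc in zip((1, -1), child_dosages, child_clones):
                ids.append(len(ids))
                parents.append(i)
                dosages.append(cd)
                born.append(gen)
                clone_ids.append(cc)
                positions.append(positions[i] + sgn * offset)
                alive.append(True)
                new_alive.append(ids[-1])
            alive[i] = False

        alive_idx = new_alive
        pos = np.array([positions[i] for i in alive_idx])
        dos = np.array([dosages[i] for i in alive_idx])
        pos, spacing = reposition(pos, dos, rng)
        for k, i in enumerate(alive_idx):
            positions[i] = pos[k]

    return SyntheticCulture(
        ids=np.array(ids),
        parents=np.array(parents),
        dosages=np.array(dosages),
        born=np.array(born),
        clone_ids=np.array(clone_ids),
        positions=np.array(positions),
        alive=np.array(alive),
        params=params,
        seed=seed,
        n_generations=gen,
        n_recombinations=n_recomb,
        meta={"recombination_onset": onset, "final_spacing": spacing},
    )


def _filtered_spring_edges(pos: np.ndarray) -> np.ndarray:
    """Delaunay edges with hull slivers removed by the max-angle rule.

    An edge survives if at least one incident triangle has all interior
    angles <= MAX_SLIVER_ANGLE_DEG; thin triangles spanning concavities of
    the hull connect distant cells and are dropped.
    """
    tri = Delaunay(pos)
    keep: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        pts = pos[simplex]
        # interior angles via the law of cosines
        good = True
        for v in range(3):
            a = pts[(v + 1) % 3] - pts[v]
            b = pts[(v + 2) % 3] - pts[v]
            cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-300)
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > MAX_SLIVER_ANGLE_DEG:
                good = False
                break
        if good:
            for u, v in ((0, 1), (1, 2), (0, 2)):
                e = (min(simplex[u], simplex[v]), max(simplex[u], simplex[v]))
                keep.add(e)
    if not keep:  # every triangle a sliver: fall back to all edges
        for simplex in tri.simplices:
            for u, v in ((0, 1), (1, 2), (0, 2)):
                keep.add((min(simplex[u], simplex[v]), max(simplex[u], simplex[v])))
    return np.array(sorted(keep))


def reposition(
    positions: np.ndarray,
    dosages: np.ndarray,
    rng: np.random.Generator | None = None,
    n_iter: int = SPRING_ITERATIONS,
) -> tuple[np.ndarray, float]:
    """Force-directed spring relaxation toward uniform density.

    Springs connect Delaunay neighbors (slivers filtered); the rest length
    is the median edge length, springs between same-dosage neighbors are
    10% stiffer, and positions are updated for a fixed iteration budget
    with step damping.  Returns (new positions, rest length).
    """
    pos = np.asarray(positions, dtype=float).copy()
    if rng is None:
        rng = np.random.default_rng()
    n = len(pos)
    if n < 2:
        return pos, REST_LENGTH_DEFAULT
    if n == 2:
        rest = REST_LENGTH_DEFAULT
        mid = pos.mean(axis=0)
        d = pos[1] - pos[0]
        nrm = np.linalg.norm(d)
        u = d / nrm if nrm > 0 else np.array([1.0, 0.0])
        pos[0] = mid - 0.5 * rest * u
        pos[1] = mid + 0.5 * rest * u
        return pos, rest

    edges = None
    for _ in range(5):  # jittered retry on degenerate geometry
        try:
            edges = _filtered_spring_edges(pos)
            break
        except QhullError:
            pos = pos + rng.normal(scale=1e-3, size=pos.shape)
    if edges is None:
        raise ParameterError("could not triangulate cell positions")

    i, j = edges[:, 0], edges[:, 1]
    lengths = np.linalg.norm(pos[i] - pos[j], axis=1)
    rest = float(np.median(lengths))
    if rest == 0:
        rest = REST_LENGTH_DEFAULT
    stiffness = np.where(
        np.asarray(dosages)[i] == np.asarray(dosages)[j], SAME_DOSAGE_STIFFNESS, 1.0
    )
    step = SPRING_STEP
    for it in range(n_iter):
        delta = pos[j] - pos[i]
        dist = np.linalg.norm(delta, axis=1)
        dist[dist == 0] = 1e-12
        unit = delta / dist[:, None]
        f = (stiffness * (dist - rest))[:, None] * unit  # pull i toward j if stretched
        force = np.zeros_like(pos)
        np.add.at(force, i, f)
        np.add.at(force, j, -f)
        pos += step * (0.98**it) * force
    return pos, rest


def sample_fluorescence(
    dosages: np.ndarray, fp: FluorescenceParams | None = None, seed: int | None = None
) -> np.ndarray:
    """Marker levels x with ln x ~ N(mu_n, sigma_alpha^2) per cell."""
    if fp is None:
        fp = FluorescenceParams()
    rng = np.random.default_rng(seed)
    mu = FluorescenceParams.mu(dosages)
    return np.exp(rng.normal(mu, fp.sigma_alpha))


def synthesize_measurements(
    culture: SyntheticCulture,
    fp: FluorescenceParams | None = None,
    seed: int | None = None,
    control_bleed_alpha: float | None = None,
    control_sigma: float = 0.2,
) -> MeasurementTable:
    """Measurement table for the final population of a culture.

    Channels: ch0 = nuclear stain (uniform), ch1 = clonal marker (sampled
    from the dosage-conditioned lognormal).  If ``control_bleed_alpha`` is
    given a dosage-independent control reporter is added as ch2 with an
    injected linear bleedthrough contribution alpha * ch1, emulating a
    bleedthrough control experiment.  Ground truth is kept in the
    ``true_dosage`` column; ``dosage`` is left unset for the annotator.
    """
    rng = np.random.default_rng(seed)
    dosages = culture.alive_dosages
    marker = sample_fluorescence(dosages, fp, seed=rng.integers(2**31))
    pos = culture.alive_positions
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, len(dosages) + 1),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "ch0": np.ones(len(dosages)),
            "ch1": marker,
            "true_dosage": dosages,
            "clone_id": culture.alive_clone_ids,
        }
    )
    if control_bleed_alpha is not None:
        control = np.exp(rng.normal(0.0, control_sigma, len(dosages)))
        df["ch2"] = control + control_bleed_alpha * marker
    return MeasurementTable(df)


def render_image(
    culture_or_positions,
    marker_levels: np.ndarray,
    image_size: int = 512,
    nucleus_radius: int = 5,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a 2-channel synthetic image (stain, marker) of disk nuclei.

    The stain channel holds uniform-intensity disks; in the marker channel
    each disk is shaded by the cell's sampled fluorescence level.  Additive
    Gaussian read noise is optional.  Returns ``(image, positions_px)``
    where image has shape (2, H, W) and positions are the (x, y) disk
    centers in pixels.
    """
    from skimage.draw import disk as draw_disk

    pos = (
        culture_or_positions.alive_positions
        if isinstance(culture_or_positions, SyntheticCulture)
        else np.asarray(culture_or_positions, dtype=float)
    )
    marker_levels = np.asarray(marker_levels, dtype=float)
    margin = 2 * nucleus_radius + 2
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    scale = (image_size - 2 * margin) / span.max()
    px = (pos - lo) * scale + margin

    if len(px) > 1:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(px).query(px, k=2)
        min_spacing = d[:, 1].min()
        if nucleus_radius > min_spacing / 2:
            warnings.warn(
                "nucleus radius exceeds half the minimum cell spacing; "
                "rendered nuclei will overlap",
                stacklevel=2,
            )

    image = np.zeros((2, image_size, image_size), dtype=float)
    for (x, y), level in zip(px, marker_levels):
        rr, cc = draw_disk((y, x), nucleus_radius, shape=(image_size, image_size))
        image[0, rr, cc] = 1.0
        image[1, rr, cc] = level
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + rng.normal(0, noise_sigma, image.shape), 0, None)
    return image, px


def mean_clone_size(culture: SyntheticCulture) -> float:
    """Final population size divided by the number of clones.

    Clones are the lineage subtrees founded at recombination events plus
    the residual dosage-1 population.
    """
    clones = np.unique(culture.alive_clone_ids)
    return culture.n_alive / len(clones)
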