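"""Ground-truthed simulation of dual-tag rolling-circle proximity assays.

The simulator emulates fields of fixed cells: elliptical nuclei inside
elliptical cytoplasms with a membrane band, ground-truth molecules (free
protein A, free protein B, AB complexes) placed per compartment, and the
molecular cascade that turns molecules into rolling-circle products (RCPs):
antibody binding (epitope occupancy), proximity gating, circle hybridization,
nicking, tag incorporation, ligation and amplification — each an explicit
Bernoulli efficiency. Three assay modes are modeled:

``molboolean``
    the dual-tag assay: a complex bound by both probes within the proximity
    threshold yields a dual-tag RCP; free proteins yield single-tag RCPs.
``pla``
    in situ proximity ligation: only dual-bound proximal pairs can emit an
    (single-channel) event; free proteins are invisible.
``padlock``
    the single-reporter control: every bound probe independently emits its
    own singleton RCP, never a dual.

All stochastic draws flow from one seed through named substreams so that
placement, binding and rendering are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeometryConfig",
    "CellGeometry",
    "Field",
    "PopulationSpec",
    "AssayParams",
    "make_field",
    "place_molecules",
    "simulate_molecular_events",
    "expected_fractions",
    "substreams",
]

MOLECULE_CLASSES = ("freeA", "freeB", "complex")
EVENT_CATEGORIES = ("freeA", "freeB", "complex")


def substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Independent named random substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _as_rng(rng: "np.random.Generator | int") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of the synthetic cell field (pixel units unless noted)."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = 100.0
    nucleus_radius_px: tuple[float, float] = (28.0, 34.0)
    #: cytoplasm semi-axes as a multiple of the nucleus semi-axes
    cyto_scale: tuple[float, float] = (2.8, 3.2)
    membrane_width_px: int = 4
    min_gap_px: float = 6.0


@dataclass(frozen=True)
class CellGeometry:
    cell_id: int
    center_px: tuple[float, float]  # (y, x)
    nucleus_axes_px: tuple[float, float]
    cyto_axes_px: tuple[float, float]
    angle_rad: float


@dataclass
class Field:
    """A simulated cell field: per-compartment label images plus geometry.

    ``cell_labels`` covers the whole cell (nucleus included); compartments
    partition it into ``nucleus_labels``, ``membrane_labels`` (the outer band
    of the cytoplasm) and the remaining cytoplasm proper.
    """

    config: GeometryConfig
    cells: list[CellGeometry]
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    membrane_labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def compartment_mask(self, compartment: str, cell_id: int) -> np.ndarray:
        if compartment == "nucleus":
            return self.nucleus_labels == cell_id
        if compartment == "membrane":
            return self.membrane_labels == cell_id
        if compartment == "cytoplasm":
            return (
                (self.cell_labels == cell_id)
                & (self.nucleus_labels != cell_id)
                & (self.membrane_labels != cell_id)
            )
        raise ValueError(f"unknown compartment {compartment!r}")


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    cy, cx = center
    a, b = axes
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy - r)), min(shape[0], int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(shape[1], int(cx + r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def make_field(
    n_cells: int,
    config: GeometryConfig = GeometryConfig(),
    rng: "np.random.Generator | int" = 0,
) -> Field:
    """Place ``n_cells`` non-overlapping cells on a jittered grid.

    Deterministic under a fixed seed. Raises when the requested number of
    cells cannot fit in the frame without overlap.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = _as_rng(rng)
    H, W = config.shape
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    cell_labels = np.zeros((H, W), dtype=np.int32)
    membrane_labels = np.zeros((H, W), dtype=np.int32)
    cells: list[CellGeometry] = []
    if n_cells == 0:
        return Field(config, cells, nucleus_labels, cell_labels, membrane_labels)

    cols = int(np.ceil(np.sqrt(n_cells * W / H)))
    rows = int(np.ceil(n_cells / cols))
    pitch_y, pitch_x = H / rows, W / cols
    max_cyto = config.nucleus_radius_px[1] * config.cyto_scale[1]
    if min(pitch_y, pitch_x) < 2 * max_cyto + config.min_gap_px:
        raise ValueError(
            f"cannot place {n_cells} non-overlapping cells of radius "
            f"~{max_cyto:.0f} px in a {H}x{W} frame"
        )
    order = rng.permutation(rows * cols)[:n_cells]
    for cell_id, k in enumerate(np.sort(order), start=1):
        gy, gx = divmod(int(k), cols)
        rn_a = rng.uniform(*config.nucleus_radius_px)
        rn_b = rn_a * rng.uniform(0.8, 1.0)
        scale = rng.uniform(*config.cyto_scale)
        rc_a, rc_b = rn_a * scale, rn_b * scale
        angle = rng.uniform(0, np.pi)
        slack_y = pitch_y / 2 - max(rc_a, rc_b) - config.min_gap_px / 2
        slack_x = pitch_x / 2 - max(rc_a, rc_b) - config.min_gap_px / 2
        cy = (gy + 0.5) * pitch_y + rng.uniform(-1, 1) * max(slack_y, 0)
        cx = (gx + 0.5) * pitch_x + rng.uniform(-1, 1) * max(slack_x, 0)
        cyto = _ellipse_mask((H, W), (cy, cx), (rc_a, rc_b), angle)
        inner = _ellipse_mask(
            (H, W),
            (cy, cx),
            (rc_a - config.membrane_width_px, rc_b - config.membrane_width_px),
            angle,
        )
        nucleus = _ellipse_mask((H, W), (cy, cx), (rn_a, rn_b), angle)
        cell_labels[cyto] = cell_id
        membrane_labels[cyto & ~inner] = cell_id
        nucleus_labels[nucleus] = cell_id
        cells.append(CellGeometry(cell_id, (cy, cx), (rn_a, rn_b), (rc_a, rc_b), angle))
    return Field(config, cells, nucleus_labels, cell_labels, membrane_labels)


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth molecule population per cell.

    Defaults describe a moderately expressed cytosolic interaction pair at
    RCP-countable density (~50 signals per cell, complex fraction 0.4); a
    junction-forming pair is emulated by directing the ``complex`` class to
    the ``membrane`` compartment. With ``count_model="poisson"`` per-cell
    counts are Poisson draws around the stated means (biological cell-to-cell
    variability); ``"fixed"`` places the exact counts in every cell.
    """

    n_free_a: float = 15
    n_free_b: float = 15
    n_complex: float = 20
    compartments: Mapping[str, str] = field(
        default_factory=lambda: {
            "freeA": "cytoplasm",
            "freeB": "cytoplasm",
            "complex": "cytoplasm",
        }
    )
    count_model: str = "fixed"

    def counts(self) -> dict[str, float]:
        return {
            "freeA": self.n_free_a,
            "freeB": self.n_free_b,
            "complex": self.n_complex,
        }


def place_molecules(
    field: Field,
    spec: PopulationSpec = PopulationSpec(),
    rng: "np.random.Generator | int" = 0,
) -> pd.DataFrame:
    """Place ground-truth molecules uniformly within their compartments.

    Returns one row per molecule with nm positions (pixel-centered grid:
    ``x_nm = (x_px + 0.5) * pixel_size``), the molecule class, compartment
    and owning cell. Counts per cell follow the population spec exactly
    (``"fixed"``) or as Poisson draws (``"poisson"``).
    """
    rng = _as_rng(rng)
    px = field.config.pixel_size_nm
    rows = []
    mol_id = 0
    for cell in field.cells:
        for mol_class in MOLECULE_CLASSES:
            mean = spec.counts()[mol_class]
            if spec.count_model == "poisson":
                n = int(rng.poisson(mean))
            elif spec.count_model == "fixed":
                n = int(round(mean))
            else:
                raise ValueError(f"unknown count_model {spec.count_model!r}")
            if n == 0:
                continue
            compartment = spec.compartments[mol_class]
            mask = field.compartment_mask(compartment, cell.cell_id)
            pixels = np.argwhere(mask)
            if len(pixels) == 0:
                raise ValueError(
                    f"compartment {compartment!r} of cell {cell.cell_id} is empty"
                )
            chosen = pixels[rng.integers(0, len(pixels), size=n)]
            sub = rng.uniform(0, 1, size=(n, 2))
            yx = (chosen + sub) * px
            for (y_nm, x_nm) in yx:
                rows.append(
                    {
                        "molecule_id": mol_id,
                        "cell_id": cell.cell_id,
                        "mol_class": mol_class,
                        "compartment": compartment,
                        "x_nm": float(x_nm),
                        "y_nm": float(y_nm),
                    }
                )
                mol_id += 1
    columns = ["molecule_id", "cell_id", "mol_class", "compartment", "x_nm", "y_nm"]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class AssayParams:
    """Probabilistic parameters of the molecular cascade.

    Occupancies are the probabilities that an epitope is antibody-bound; the
    proximity threshold is the maximal epitope separation allowing one circle
    to bridge both probes (40 nm for secondary probes, 30 nm for primary);
    ``separation_max_nm`` is the upper bound of the uniform epitope-separation
    draw within a complex. Enzymatic efficiencies default to 1 (the enzymatic
    steps are highly efficient) and are explicit knobs.
    """

    occupancy_a: float = 1.0
    occupancy_b: float = 1.0
    proximity_threshold_nm: float = 40.0
    separation_max_nm: float = 20.0
    e_circle: float = 1.0
    e_nick: float = 1.0
    e_tag: float = 1.0
    e_ligate: float = 1.0
    e_rca: float = 1.0
    mode: str = "molboolean"

    def __post_init__(self) -> None:
        for name in ("occupancy_a", "occupancy_b", "e_circle", "e_nick", "e_tag", "e_ligate", "e_rca"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.proximity_threshold_nm <= 0:
            raise ValueError("proximity_threshold_nm must be > 0")
        if self.separation_max_nm < 0:
            raise ValueError("separation_max_nm must be >= 0")
        if self.mode not in ("molboolean", "pla", "padlock"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def p_proximal(self) -> float:
        """P(epitope separation <= proximity threshold) within a complex."""
        if self.separation_max_nm <= 0:
            return 1.0
        return min(1.0, self.proximity_threshold_nm / self.separation_max_nm)


_EVENT_COLUMNS = [
    "event_id",
    "cell_id",
    "x_nm",
    "y_nm",
    "tags",
    "category",
    "source_ids",
    "mechanism",
]

_TAG_TO_CATEGORY = {"A": "freeA", "B": "freeB", "AB": "complex"}


def _collect(molecules: pd.DataFrame, pieces: list[tuple[np.ndarray, np.ndarray]], mode: str, categories: "list[np.ndarray] | None" = None) -> pd.DataFrame:
    """Assemble the event table from (molecule index mask, tag array) pieces."""
    frames = []
    for k, (idx, tags) in enumerate(pieces):
        sub = molecules.iloc[idx]
        cat = (
            categories[k]
            if categories is not None
            else np.vectorize(_TAG_TO_CATEGORY.get)(tags) if len(tags) else tags
        )
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": sub["cell_id"].to_numpy(),
                    "x_nm": sub["x_nm"].to_numpy(),
                    "y_nm": sub["y_nm"].to_numpy(),
                    "tags": tags,
                    "category": cat,
                    "source_ids": sub["molecule_id"].astype(str).to_numpy(),
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=[c for c in _EVENT_COLUMNS if c not in ("event_id", "mechanism")])
    df["mechanism"] = mode
    df.insert(0, "event_id", np.arange(len(df)))
    return df[_EVENT_COLUMNS]


def simulate_molecular_events(
    molecules: pd.DataFrame,
    params: AssayParams = AssayParams(),
    rng: "np.random.Generator | int" = 0,
) -> pd.DataFrame:
    """Draw the molecular cascade for every ground-truth molecule.

    Returns one row per rolling-circle product with its tag content
    (``"A"``, ``"B"`` or ``"AB"``), truth category, source molecule ids and
    generating mechanism. See :func:`expected_fractions` for the closed-form
    expectations of the same generative rules.
    """
    rng = _as_rng(rng)
    p = params
    en = p.e_circle * p.e_nick
    el = p.e_ligate * p.e_rca
    cls = molecules["mol_class"].to_numpy()
    n = len(molecules)
    is_a = cls == "freeA"
    is_b = cls == "freeB"
    is_c = cls == "complex"

    def bern(prob: float, size: int) -> np.ndarray:
        return rng.random(size) < prob

    pieces: list[tuple[np.ndarray, np.ndarray]] = []

    if p.mode == "padlock":
        # every bound probe independently emits its own singleton RCP
        s = p.e_circle * p.e_ligate * p.e_rca
        emit_a = (is_a | is_c) & bern(p.occupancy_a * s, n)
        emit_b = (is_b | is_c) & bern(p.occupancy_b * s, n)
        ia, ib = np.flatnonzero(emit_a), np.flatnonzero(emit_b)
        pieces = [(ia, np.full(len(ia), "A")), (ib, np.full(len(ib), "B"))]
        return _collect(molecules, pieces, p.mode)

    if p.mode == "pla":
        # only dual-bound proximal pairs emit (single-channel reporter)
        s = p.e_circle * p.e_ligate * p.e_rca
        sep = (
            rng.uniform(0, p.separation_max_nm, n)
            if p.separation_max_nm > 0
            else np.zeros(n)
        )
        emit = (
            is_c
            & bern(p.occupancy_a, n)
            & bern(p.occupancy_b, n)
            & (sep <= p.proximity_threshold_nm)
            & bern(s, n)
        )
        idx = np.flatnonzero(emit)
        return _collect(
            molecules,
            [(idx, np.full(len(idx), "A"))],
            p.mode,
            categories=[np.full(len(idx), "complex")],
        )

    # molboolean
    bound_a = bern(p.occupancy_a, n)
    bound_b = bern(p.occupancy_b, n)
    sep = (
        rng.uniform(0, p.separation_max_nm, n)
        if p.separation_max_nm > 0
        else np.zeros(n)
    )
    single_path = bern(en, n) & bern(p.e_tag, n) & bern(el, n)

    emit_free_a = is_a & bound_a & single_path
    emit_free_b = is_b & bound_b & single_path

    dual_elig = is_c & bound_a & bound_b & (sep <= p.proximity_threshold_nm)
    nick_a = bern(en, n)
    nick_b = bern(en, n)
    seal_a = ~nick_a | bern(p.e_tag, n)
    seal_b = ~nick_b | bern(p.e_tag, n)
    # an open (formed but unsealed) nick leaves the circle non-amplifiable
    dual_emit = dual_elig & (nick_a | nick_b) & seal_a & seal_b & bern(el, n)
    dual_tags = np.where(
        nick_a & nick_b, "AB", np.where(nick_a, "A", "B")
    )

    # one engaged probe: one bound, or both bound but distal (either arm 1/2)
    one_bound = is_c & (bound_a ^ bound_b)
    distal = is_c & bound_a & bound_b & (sep > p.proximity_threshold_nm)
    pick_a = bern(0.5, n)
    single_arm_a = (one_bound & bound_a) | (distal & pick_a)
    single_arm_b = (one_bound & bound_b) | (distal & ~pick_a)
    emit_single_c = (single_arm_a | single_arm_b) & single_path
    single_tags = np.where(single_arm_a, "A", "B")

    ia = np.flatnonzero(emit_free_a)
    ib = np.flatnonzero(emit_free_b)
    idual = np.flatnonzero(dual_emit)
    isng = np.flatnonzero(emit_single_c)
    pieces = [
        (ia, np.full(len(ia), "A")),
        (ib, np.full(len(ib), "B")),
        (idual, dual_tags[idual]),
        (isng, single_tags[isng]),
    ]
    return _collect(molecules, pieces, p.mode)


def expected_fractions(
    params: AssayParams,
    spec: PopulationSpec = PopulationSpec(),
) -> dict:
    """Closed-form expectations of :func:`simulate_molecular_events`.

    Derivation (molboolean mode), writing ``en = e_circle*e_nick``,
    ``et = e_tag``, ``el = e_ligate*e_rca``, ``q = P(separation <=
    threshold)`` and ``s1 = en*et*el`` for the single-arm path:

    - a free molecule emits its singleton with probability ``occ * s1``;
    - a dual-eligible complex (both probes bound and proximal, probability
      ``pA*pB*q``) emits a dual event when both nicks form and seal
      (``(en*et)^2 * el``), and an A-singleton when nick A forms and seals
      while nick B never forms (``en*et*(1-en)*el``) — a formed-but-unsealed
      nick voids the circle;
    - a complex with exactly one probe engaged (one bound, or both bound but
      distal, in which case the circle engages either arm with probability
      1/2) follows the single-arm path ``s1``.

    Returns per-molecule-class event probabilities and expected event counts
    per category for the population spec (per cell).
    """
    p = params
    en = p.e_circle * p.e_nick
    et = p.e_tag
    el = p.e_ligate * p.e_rca
    q = p.p_proximal
    pa, pb = p.occupancy_a, p.occupancy_b
    s1 = en * et * el

    if p.mode == "padlock":
        s = p.e_circle * p.e_ligate * p.e_rca
        probs = {
            "freeA_given_freeA": pa * s,
            "freeB_given_freeB": pb * s,
            "dual_given_complex": 0.0,
            "freeA_given_complex": pa * s,
            "freeB_given_complex": pb * s,
        }
    elif p.mode == "pla":
        s = p.e_circle * p.e_ligate * p.e_rca
        probs = {
            "freeA_given_freeA": 0.0,
            "freeB_given_freeB": 0.0,
            "dual_given_complex": pa * pb * q * s,
            "freeA_given_complex": 0.0,
            "freeB_given_complex": 0.0,
        }
    else:
        dual = pa * pb * q * (en * et) ** 2 * el
        single_a = pa * pb * q * en * et * (1 - en) * el
        single_a += (pa * (1 - pb) + pa * pb * (1 - q) * 0.5) * s1
        single_b = pa * pb * q * en * et * (1 - en) * el
        single_b += ((1 - pa) * pb + pa * pb * (1 - q) * 0.5) * s1
        probs = {
            "freeA_given_freeA": pa * s1,
            "freeB_given_freeB": pb * s1,
            "dual_given_complex": dual,
            "freeA_given_complex": single_a,
            "freeB_given_complex": single_b,
        }
    counts = spec.counts()
    expected = {
        "freeA": counts["freeA"] * probs["freeA_given_freeA"]
        + counts["complex"] * probs["freeA_given_complex"],
        "freeB": counts["freeB"] * probs["freeB_given_freeB"]
        + counts["complex"] * probs["freeB_given_complex"],
        "complex": counts["complex"] * probs["dual_given_complex"],
    }
    return {"probabilities": probs, "expected_counts": expected}
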