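"""Ground-truth-known polarimetric scene simulation.

Scenes emulate a six-date, five-class rice-growing study area: water,
urban, shoal naked land (SNL), transplanted hybrid rice (T-H) and
direct-sown japonica rice (D-J).  Each class-date combination is a
scattering-mechanism mixture — power fractions of surface, double-bounce
and volume scattering with a co-polar ratio and coherence — turned into a
3x3 lexicographic covariance C3.  Pixels are fully developed speckle:
i.i.d. zero-mean circular complex Gaussian scattering vectors with that
covariance (so multilook averages follow Wishart statistics).

The default phenology schedule encodes the canonical crop narrative:
surface-dominated seedlings over flooded (T-H) or moist-soil (D-J)
ground; a sharp rise of volume + double-bounce scattering to elongation;
a slight dip at booting as the denser canopy suppresses double bounce; a
plateau through maturity; then a harvest-date split — T-H reverts to a
bare-soil surface response while the longer-cycle D-J is still standing.
Class separability between the two rice types therefore peaks on the
final (harvest) date.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from genpol.compact import transmit_wave
from genpol.exceptions import DomainError, ValidationError
from genpol.io import LabelMask, ScatteringImage

CLASS_NAMES = ["water", "urban", "SNL", "T-H", "D-J"]
DATE_TAGS = ["0612", "0730", "0823", "0916", "1010", "1103"]
DOY = [163, 211, 235, 259, 283, 307]
STAGES = ["Seedling", "Seedling-Elongation", "Booting-Heading",
          "Heading-Flowering", "Dough-Mature", "Harvest"]


# ---------------------------------------------------------------------------
# canonical targets and mixture covariances
# ---------------------------------------------------------------------------

def canonical_target(kind: str) -> np.ndarray:
    """Single-pixel 2x2 Sinclair matrix of an ideal scatterer."""
    if kind == "trihedral":
        return np.array([[1.0, 0.0], [0.0, 1.0]], dtype=complex)
    if kind == "dihedral":
        return np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
    if kind == "hv_pair":
        return np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
    raise DomainError(f"unknown canonical target {kind!r}")


def constant_scene(s: np.ndarray, shape: tuple[int, int] = (1, 1),
                   date_tag: str = "") -> ScatteringImage:
    """Tile one Sinclair matrix into a constant scattering image."""
    ones = np.ones(shape)
    return ScatteringImage(s[0, 0] * ones, s[0, 1] * ones,
                           s[1, 0] * ones, s[1, 1] * ones, date_tag=date_tag)


@dataclass
class MixtureSpec:
    """Scattering-mechanism mixture: power fractions (sum to 1), co-polar
    power ratio <|S_VV|^2>/<|S_HH|^2> of the coherent part, co-polar
    coherence magnitude, and total power (linear units)."""

    f_surface: float
    f_double: float
    f_volume: float
    copol_ratio: float = 1.0
    copol_coherence: complex = 0.9
    total_power: float = 1.0

    def __post_init__(self) -> None:
        fr = (self.f_surface, self.f_double, self.f_volume)
        if min(fr) < 0:
            raise ValidationError("mixture fractions must be nonnegative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"mixture fractions sum to {sum(fr)}, not 1")
        if self.copol_ratio <= 0:
            raise ValidationError("copol_ratio must be positive")
        if abs(self.copol_coherence) > 1 + 1e-12:
            raise ValidationError("|copol_coherence| must be <= 1")
        if self.total_power <= 0:
            raise ValidationError("total_power must be positive")


def _copol_block(ratio: float, coherence: complex) -> np.ndarray:
    """Unit-trace co-polar covariance in the (HH, sqrt2*HV, VV) basis."""
    g = ratio
    c = coherence * np.sqrt(g)
    m = np.array([[1.0, 0.0, np.conj(c)],
                  [0.0, 0.0, 0.0],
                  [c, 0.0, g]], dtype=complex)
    return m / (1.0 + g)


#: Azimuthally symmetric random-volume covariance: co-polar channels
#: decorrelated and equal power, one third of the power in cross-pol.
VOLUME_C3 = np.eye(3, dtype=complex) / 3.0


def mixture_covariance(spec: MixtureSpec) -> np.ndarray:
    """3x3 Hermitian PSD covariance (lexicographic basis) of the mixture.

    Surface and double-bounce parts share the co-polar ratio; double
    bounce carries the opposite co-polar phase (coherence negated), the
    +-pi phase signature of an even number of bounces.
    """
    c3 = (spec.f_surface * _copol_block(spec.copol_ratio, spec.copol_coherence)
          + spec.f_double * _copol_block(spec.copol_ratio,
                                         -spec.copol_coherence)
          + spec.f_volume * VOLUME_C3)
    c3 *= spec.total_power
    w = np.linalg.eigvalsh(c3)
    if w.min() < -1e-10 * max(w.max(), 1e-300):
        raise ValidationError("mixture covariance is not PSD")  # unreachable
    return c3


# ---------------------------------------------------------------------------
# closed-form decomposition parameters of a covariance
# ---------------------------------------------------------------------------

_PAULI = np.array([[1, 0, 1], [1, 0, -1], [0, np.sqrt(2), 0]],
                  dtype=complex) / np.sqrt(2)


def analytic_t3(c3: np.ndarray) -> np.ndarray:
    """Pauli coherency T3 of a lexicographic covariance C3."""
    return _PAULI @ np.asarray(c3, dtype=complex) @ _PAULI.conj().T


def analytic_alpha_b(c3: np.ndarray) -> float:
    """Closed-form alpha_B (degrees) of an ensemble with covariance C3."""
    t3 = analytic_t3(c3)
    return float(np.degrees(np.arctan2(t3[1, 1].real + t3[2, 2].real,
                                       t3[0, 0].real)))


def analytic_cp_moments(c3: np.ndarray, theta: float, chi: float
                        ) -> tuple[float, float, complex]:
    """(<|E1|^2>, <|E2|^2>, <E2 E1*>) of the CP channels at (theta, chi)."""
    w = transmit_wave(theta, chi)
    # E1 = HH + (b/a) HV, E2 = VV + (a/b) HV with HV = lex[1]/sqrt(2)
    u1 = np.array([1.0, (w.b / w.a) / np.sqrt(2), 0.0], dtype=complex)
    u2 = np.array([0.0, (w.a / w.b) / np.sqrt(2), 1.0], dtype=complex)
    c3 = np.asarray(c3, dtype=complex)
    p1 = float((u1.conj() @ c3 @ u1).real)
    p2 = float((u2.conj() @ c3 @ u2).real)
    cross = complex(u2.conj() @ c3 @ u1)   # <E2 E1*>
    return p1, p2, cross

def analytic_alpha_bcp(c3: np.ndarray, theta: float, chi: float) -> float:
    """Closed-form alpha_BCP (degrees) at transmit ellipse (theta, chi)."""
    p1, p2, cross = analytic_cp_moments(c3, theta, chi)
    num = p1 + p2 - 2.0 * cross.real      # <|E1 - E2|^2>
    den = p1 + p2 + 2.0 * cross.real      # <|E1 + E2|^2>
    return float(np.degrees(np.arctan2(max(num, 0.0), max(den, 0.0))))


# ---------------------------------------------------------------------------
# speckle sampling
# ---------------------------------------------------------------------------

def sample_speckle(c3: np.ndarray, shape: tuple[int, int],
                   seed: int | np.random.Generator,
                   date_tag: str = "") -> ScatteringImage:
    """Fully developed speckle with covariance c3.

    Draws i.i.d. zero-mean circular complex Gaussian lexicographic
    vectors (HH, sqrt2*HV, VV); rank-deficient covariances are handled by
    an eigendecomposition square root.  The cross channels satisfy
    S_VH = S_HV exactly.  Deterministic for a fixed integer seed
    (PCG64 via numpy's default generator).
    """
    c3 = np.asarray(c3, dtype=complex)
    w, v = np.linalg.eigh(c3)
    if w.min() < -1e-10 * max(w.max(), 1e-300):
        raise DomainError("covariance is not positive semidefinite")
    root = v * np.sqrt(np.maximum(w, 0.0))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = shape[0] * shape[1]
    g = rng.standard_normal((3, n)) + 1j * rng.standard_normal((3, n))
    z = (root @ (g / np.sqrt(2.0))).reshape(3, *shape)
    hv = z[1] / np.sqrt(2.0)
    return ScatteringImage(z[0], hv, hv.copy(), z[2], date_tag=date_tag)


# ---------------------------------------------------------------------------
# parcel layout and phenology schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Parcel:
    """A surveyed sample parcel: the labeled core of a larger homogeneous
    field.  ``margin`` extends the field's texture beyond the labeled
    rectangle so that window-based estimators see pure statistics at the
    core (survey parcels are drawn well inside fields, not at hedgerows).
    """

    row0: int
    col0: int
    height: int
    width: int
    class_id: int       # 1-based index into CLASS_NAMES
    split: str          # "train" | "verify"
    margin: int = 0

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))

    def field_slices(self, rows: int, cols: int) -> tuple[slice, slice]:
        return (slice(max(self.row0 - self.margin, 0),
                      min(self.row0 + self.height + self.margin, rows)),
                slice(max(self.col0 - self.margin, 0),
                      min(self.col0 + self.width + self.margin, cols)))


@dataclass
class ParcelLayout:
    rows: int
    cols: int
    parcels: list[Parcel]
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self) -> None:
        cover = np.zeros((self.rows, self.cols), dtype=bool)
        counts: dict[int, int] = {}
        for p in self.parcels:
            if p.row0 < 0 or p.col0 < 0 or p.row0 + p.height > self.rows \
                    or p.col0 + p.width > self.cols:
                raise ValidationError(f"parcel {p} outside the raster")
            sl = p.field_slices(self.rows, self.cols)
            if cover[sl].any():
                raise ValidationError(f"parcel {p} overlaps another parcel")
            cover[sl] = True
            counts[p.class_id] = counts.get(p.class_id, 0) + 1
        for cid in range(1, len(self.class_names) + 1):
            if counts.get(cid, 0) < 2:
                raise ValidationError(
                    f"class {self.class_names[cid - 1]} needs >= 2 parcels "
                    "for a train/verify split")

    def label_mask(self) -> LabelMask:
        labels = np.zeros((self.rows, self.cols), dtype=np.int32)
        parcel_ids = np.zeros_like(labels)
        split: dict[int, str] = {}
        for pid, p in enumerate(self.parcels, start=1):
            sl = p.slices()
            labels[sl] = p.class_id
            parcel_ids[sl] = pid
            split[pid] = p.split
        return LabelMask(labels, list(self.class_names),
                         parcel_ids=parcel_ids, split=split)


#: Field-campaign parcel counts: 28 T-H and 14 D-J rice parcels plus 8
#: parcels each of water, urban and SNL.
DEFAULT_PARCEL_COUNTS = {"water": 8, "urban": 8, "SNL": 8, "T-H": 28, "D-J": 14}


def default_layout(parcel_size: int = 12, margin: int = 4, gap: int = 2,
                   grid_cols: int = 9) -> ParcelLayout:
    """Rectangular parcel grid with a 50/50 alternating train/verify split
    inside every class (the two sets share no parcel).

    Each labeled core sits inside a same-class field extended by
    ``margin`` pixels, so a 7x7 estimator window stays within the field
    everywhere on the core.
    """
    order: list[str] = []
    for name, n in DEFAULT_PARCEL_COUNTS.items():
        order.extend([name] * n)
    parcels = []
    per_class_seen: dict[str, int] = {}
    pitch = parcel_size + 2 * margin + gap
    for idx, name in enumerate(order):
        r, c = divmod(idx, grid_cols)
        k = per_class_seen.get(name, 0)
        per_class_seen[name] = k + 1
        parcels.append(Parcel(
            row0=gap + margin + r * pitch, col0=gap + margin + c * pitch,
            height=parcel_size, width=parcel_size,
            class_id=CLASS_NAMES.index(name) + 1,
            split="train" if k % 2 == 0 else "verify",
            margin=margin))
    n_rows = -(-len(order) // grid_cols)
    return ParcelLayout(rows=gap + n_rows * pitch,
                        cols=gap + grid_cols * pitch, parcels=parcels)


@dataclass
class PhenologySchedule:
    """Per-class, per-date mixture specifications for the six dates."""

    dates: list[str]
    stages: list[str]
    specs: dict[str, list[MixtureSpec]]

    def __post_init__(self) -> None:
        n = len(self.dates)
        if len(self.stages) != n:
            raise ValidationError("stages/dates length mismatch")
        for name, lst in self.specs.items():
            if len(lst) != n:
                raise ValidationError(
                    f"class {name} has {len(lst)} specs, expected {n}")

    def spec(self, class_name: str, date_index: int) -> MixtureSpec:
        return self.specs[class_name][date_index]


def _mix(fs, fd, fv, ratio=1.0, coh=0.9, power=1.0) -> MixtureSpec:
    return MixtureSpec(fs, fd, fv, copol_ratio=ratio,
                       copol_coherence=coh, total_power=power)


def default_phenology_schedule() -> PhenologySchedule:
    """Six-date mixtures for the five classes (see module docstring).

    Rice trajectories follow seedling -> elongation rise, slight booting
    dip, heading-maturity plateau, then the harvest split: T-H reverts to
    bare soil, D-J stays vegetated.  Water is pure specular surface,
    urban is double-bounce dominated, SNL a rough moist surface; all
    three are date-stationary.
    """
    water = [_mix(1.0, 0.0, 0.0, coh=0.98, power=0.05)] * 6
    urban = [_mix(0.10, 0.85, 0.05, coh=0.95, power=1.5)] * 6
    snl = [_mix(0.70, 0.05, 0.25, ratio=1.5, coh=0.7, power=0.3)] * 6
    th = [
        _mix(0.85, 0.05, 0.10, coh=0.92, power=0.15),   # seedling over water
        _mix(0.20, 0.35, 0.45, power=0.5),              # elongation rise
        _mix(0.25, 0.25, 0.50, power=0.6),              # booting dip
        _mix(0.24, 0.26, 0.50, power=0.6),              # heading plateau
        _mix(0.24, 0.26, 0.50, power=0.55),             # dough-mature plateau
        _mix(0.80, 0.05, 0.15, ratio=1.3, coh=0.8, power=0.25),  # harvested
    ]
    dj = [
        _mix(0.75, 0.08, 0.17, coh=0.85, power=0.2),    # seedling, moist soil
        _mix(0.20, 0.32, 0.48, power=0.5),              # elongation rise
        _mix(0.26, 0.24, 0.50, power=0.6),              # booting dip
        _mix(0.24, 0.25, 0.51, power=0.6),              # heading plateau
        _mix(0.24, 0.25, 0.51, power=0.55),             # dough-mature plateau
        _mix(0.22, 0.26, 0.52, power=0.5),              # still standing
    ]
    return PhenologySchedule(
        dates=list(DATE_TAGS), stages=list(STAGES),
        specs={"water": water, "urban": urban, "SNL": snl,
               "T-H": th, "D-J": dj})


#: Mixture for unlabeled background fill (mixed rough terrain).
BACKGROUND_SPEC = _mix(0.5, 0.15, 0.35, ratio=1.2, coh=0.6, power=0.25)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def build_scene(layout: ParcelLayout, schedule: PhenologySchedule,
                date_index: int, seed: int
                ) -> tuple[ScatteringImage, LabelMask]:
    """Speckled scene for one date: per-parcel samples from the class-date
    mixture covariance, background filled with an unlabeled texture."""
    if not 0 <= date_index < len(schedule.dates):
        raise DomainError(f"date index {date_index} out of range")
    missing = set(layout.class_names) - set(schedule.specs)
    if missing:
        raise ValidationError(f"schedule lacks classes {sorted(missing)}")
    rng = np.random.default_rng([seed, date_index])
    date_tag = schedule.dates[date_index]
    bg = sample_speckle(mixture_covariance(BACKGROUND_SPEC),
                        (layout.rows, layout.cols), rng, date_tag=date_tag)
    shh, shv, svv = bg.shh.copy(), bg.shv.copy(), bg.svv.copy()
    for p in layout.parcels:
        spec = schedule.spec(layout.class_names[p.class_id - 1], date_index)
        sl = p.field_slices(layout.rows, layout.cols)
        shape = (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        tile = sample_speckle(mixture_covariance(spec), shape, rng)
        shh[sl], shv[sl], svv[sl] = tile.shh, tile.shv, tile.svv
    img = ScatteringImage(shh, shv, shv.copy(), svv, date_tag=date_tag)
    return img, layout.label_mask()


def build_stack(layout: ParcelLayout, schedule: PhenologySchedule, seed: int
                ) -> tuple[list[ScatteringImage], LabelMask]:
    """All six dates of a scene with a shared label mask."""
    imgs = []
    mask = layout.label_mask()
    for d in range(len(schedule.dates)):
        img, _ = build_scene(layout, schedule, d, seed)
        imgs.append(img)
    return imgs, mask
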