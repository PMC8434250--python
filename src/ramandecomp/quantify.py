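"""Map fitted bands to conformational classes and compute report quantities.

Three families of read-outs:

* **Amide I secondary structure** — the 1590-1710 cm^-1 backbone C=O
  stretching envelope decomposes into beta-sheet (~1637), alpha-helix
  (~1650), random coil (~1663), beta-turn (~1677) and antiparallel
  beta-sheet (~1691) sub-bands, plus two aromatic side-chain bands
  (~1607-1610 and ~1620-1627) that are fitted but excluded from the
  structural denominator.  Each structural fraction is the sub-band area
  over the total structural area, in percent.
* **Disulfide conformers** — the 500-550 cm^-1 S-S stretch region carries
  sub-bands near 510 (gauche-gauche-gauche), 525 (trans-gauche-gauche) and
  545 cm^-1 (trans-gauche-trans); class fractions are summed member areas
  over the regional total.
* **Aromatic markers** — the tyrosine Fermi doublet height ratio
  I(855)/I(835) categorizes Tyr hydrogen bonding (0.9-1.43: both proton
  donor and acceptor; above 1.43: positive-charge acceptor; >= 2 suggests
  exposed anionic Tyr-O-), the tryptophan indole band height at 760 cm^-1
  on the normalized scale, and C-S stretch bands in 640-745 cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax

from .banddecomp import DecompositionResult, PeakComponent
from .io import Spectrum

__all__ = [
    "AssignmentScheme",
    "StructureReport",
    "ConformerReport",
    "MarkerReport",
    "AMIDE_I_SCHEME",
    "SS_CONFORMER_SCHEME",
    "MARKER_CATALOG",
    "UnassignedComponentWarning",
    "AMIDE_I_PROTOCOL",
    "SS_PROTOCOL",
    "analyze_amide_i",
    "analyze_ss_conformers",
    "quantify_amide_i",
    "quantify_ss_conformers",
    "tyrosine_doublet_ratio",
    "tryptophan_intensity",
    "detect_marker_bands",
    "feature_vector",
]

FRACTION_SUM_TOL = 1e-6

TYR_LOWER = 0.9
TYR_UPPER = 1.43
TYR_EXPOSED = 2.0


class UnassignedComponentWarning(UserWarning):
    """A fitted component fell outside every scheme window."""


@dataclass(frozen=True)
class SchemeEntry:
    label: str
    window: tuple[float, float]
    kind: str  # "structural" | "aromatic" | "conformer"
    #: literature band-position range (cm^-1); used to constrain component
    #: centers during fitting.  Defaults to the assignment window.
    band: tuple[float, float] | None = None
    #: literature band-width range (cm^-1) used as FWHM bounds during
    #: fitting; amide I protocols constrain widths to class-typical values
    #: because heavily overlapped sub-bands are otherwise non-identifiable
    fwhm_range: tuple[float, float] | None = None
    #: literature sub-band positions (cm^-1) for classes that split into
    #: several bands; the fit guarantees one component near each position
    subbands: tuple[float, ...] | None = None

    @property
    def band_window(self) -> tuple[float, float]:
        return self.band if self.band is not None else self.window


@dataclass
class AssignmentScheme:
    """Labelled wavenumber windows mapping components to classes.

    ``one_band_per_entry`` declares that each labelled window hosts a
    single physical band (the amide I convention); schemes whose classes
    split into several sub-bands (the disulfide conformers) leave it off
    and duplicate seeds in one window are all kept, their areas summed.
    """

    name: str
    entries: list[SchemeEntry]
    tolerance: float = 0.0
    one_band_per_entry: bool = False

    def __post_init__(self) -> None:
        spans = sorted(
            ((e.window[0] - self.tolerance, e.window[1] + self.tolerance, e.label) for e in self.entries)
        )
        for (l0, h0, a), (l1, h1, b) in zip(spans, spans[1:]):
            if l1 < h0:
                raise ValueError(f"windows {a!r} and {b!r} overlap after tolerance expansion")
        labels = [e.label for e in self.entries if e.kind != "aromatic"]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate structural/conformer labels")

    def assign(self, c: PeakComponent) -> SchemeEntry | None:
        for e in self.entries:
            lo, hi = e.window
            if lo - self.tolerance <= c.center <= hi + self.tolerance:
                return e
        return None


def _entries(kind: str, rows) -> list[SchemeEntry]:
    return [SchemeEntry(label, window, kind, band, fwhm) for label, window, band, fwhm in rows]


#: default amide I scheme.  The assignment ``window`` is the literature
#: band range symmetrically widened so the windows tile 1590-1710; the
#: ``band`` range is the literature position itself, used as the center
#: constraint during fitting; ``fwhm_range`` brackets the class-typical
#: band width (structural sub-bands ~15-20 cm^-1, aromatic ~9-11).
AMIDE_I_SCHEME = AssignmentScheme(
    name="amide_i",
    entries=_entries(
        "structural",
        [
            ("beta_sheet", (1630.0, 1644.0), (1634.0, 1640.0), (15.25, 16.75)),
            ("alpha_helix", (1645.0, 1656.0), (1649.0, 1652.0), (14.25, 15.75)),
            ("random_coil", (1657.0, 1670.0), (1662.0, 1664.0), (19.25, 20.75)),
            ("beta_turn", (1671.0, 1683.0), (1677.0, 1678.0), (18.25, 19.75)),
            ("abeta_sheet", (1684.0, 1696.0), (1690.0, 1692.0), (14.25, 15.75)),
        ],
    )
    + _entries(
        "aromatic",
        [
            ("aromatic_1607", (1603.0, 1613.0), (1607.0, 1610.0), (8.25, 9.75)),
            ("aromatic_1622", (1616.0, 1629.0), (1620.0, 1627.0), (10.25, 11.75)),
        ],
    ),
    one_band_per_entry=True,
)

#: default disulfide conformer scheme over the 500-550 cm^-1 S-S region;
#: band ranges bracket the curve-fitted sub-band positions reported for
#: wheat endosperm (513-514; 519-525; 531-546)
SS_CONFORMER_SCHEME = AssignmentScheme(
    name="ss_conformers",
    entries=[
        SchemeEntry("SSggg", (505.0, 517.0), "conformer", (508.0, 516.0), None, (513.5,)),
        SchemeEntry("SStgg", (517.5, 528.0), "conformer", (518.0, 527.0), None, (519.0, 524.5)),
        SchemeEntry("SStgt", (528.5, 550.0), "conformer", (529.0, 548.0), None, (532.0, 545.5)),
    ],
)

#: frozen decomposition protocols for the two study regions.  Seeding
#: smoothing adapts to the grid inside the decomposition (about a third of
#: the seed width); the amide I protocol uses a strict prominence cut and
#: pure-Gaussian sub-bands, the disulfide protocol keeps shallow minima
#: (its classes split into closely spaced sub-bands) and fits the mixing
#: fraction.
AMIDE_I_PROTOCOL = {
    "region": (1590.0, 1710.0),
    "seed_fwhm": 16.0,
    "min_prominence": 0.2,
    "shape_policy": "gaussian",
}
SS_PROTOCOL = {
    "region": (500.0, 550.0),
    "seed_fwhm": 10.0,
    "min_prominence": 0.02,
    "shape_policy": "pseudo_voigt",
}


def analyze_amide_i(s: Spectrum, scheme: "AssignmentScheme | None" = None, **overrides):
    """Decompose the amide I region and quantify secondary structure.

    Returns ``(StructureReport, DecompositionResult)``.  ``overrides``
    pass through to the decomposition.
    """
    from .banddecomp import decompose_region

    scheme = AMIDE_I_SCHEME if scheme is None else scheme
    opts = {**AMIDE_I_PROTOCOL, **overrides}
    region = opts.pop("region")
    result = decompose_region(s, region, scheme=scheme, **opts)
    return quantify_amide_i(result, scheme), result


def analyze_ss_conformers(s: Spectrum, scheme: "AssignmentScheme | None" = None, **overrides):
    """Decompose the 500-550 cm^-1 S-S region and quantify conformers.

    Returns ``(ConformerReport, DecompositionResult)``.
    """
    from .banddecomp import decompose_region

    scheme = SS_CONFORMER_SCHEME if scheme is None else scheme
    opts = {**SS_PROTOCOL, **overrides}
    region = opts.pop("region")
    result = decompose_region(s, region, scheme=scheme, **opts)
    return quantify_ss_conformers(result, scheme), result


#: characteristic endosperm marker bands (center, detection window, label)
MARKER_CATALOG = [
    (440.0, (434.0, 446.0), "pyranose_ring"),
    (480.0, (474.0, 486.0), "starch_480"),
    (640.0, (634.0, 646.0), "cs_gauche_640"),
    (670.0, (664.0, 676.0), "cs_670"),
    (702.0, (696.0, 708.0), "cs_702_sh"),
    (718.0, (712.0, 724.0), "cs_718"),
    (760.0, (754.0, 766.0), "trp_760"),
    (835.0, (829.0, 841.0), "tyr_835"),
    (855.0, (849.0, 861.0), "tyr_855"),
    (940.0, (934.0, 946.0), "starch_940"),
    (1127.0, (1121.0, 1133.0), "polysaccharide_1127"),
    (1380.0, (1374.0, 1386.0), "polysaccharide_1380"),
    (1460.0, (1450.0, 1470.0), "ch_deformation_1460"),
    (1660.0, (1650.0, 1670.0), "amide_i_1660"),
]


@dataclass
class StructureReport:
    """Secondary-structure fractions from one amide I decomposition."""

    fractions: dict[str, float]
    aromatic_areas: dict[str, float]
    unassigned: list[PeakComponent]
    scheme_name: str

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > FRACTION_SUM_TOL:
            raise ValueError(f"structural fractions sum to {total}, not 100")


@dataclass
class ConformerReport:
    """Disulfide-bridge conformer fractions from the S-S region."""

    fractions: dict[str, float]
    member_bands: dict[str, list[float]]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 100.0) > FRACTION_SUM_TOL:
            raise ValueError(f"conformer fractions sum to {total}, not 100")


@dataclass
class MarkerReport:
    """Aromatic / side-chain marker indices."""

    tyr_ratio: float | None = None
    tyr_category: str | None = None
    tyr_exposed_anionic: bool = False
    trp_intensity: float | None = None
    cs_bands: list[float] = field(default_factory=list)
    detected: list[dict] = field(default_factory=list)


def _fractions_from_areas(groups: dict[str, float]) -> dict[str, float]:
    total = sum(groups.values())
    if total <= 0:
        raise ValueError("zero total area; nothing to quantify")
    fracs = {k: 100.0 * v / total for k, v in groups.items()}
    # pin the largest term so the sum is exactly 100 despite rounding
    drift = 100.0 - sum(fracs.values())
    if fracs and drift != 0.0:
        kmax = max(fracs, key=fracs.get)
        fracs[kmax] += drift
    return fracs


def quantify_amide_i(d: DecompositionResult, scheme: AssignmentScheme = AMIDE_I_SCHEME) -> StructureReport:
    """Secondary-structure fractions from an amide I decomposition.

    Components are assigned to the scheme window containing their center
    (within the scheme tolerance).  Fractions are percentages of the total
    *structural* area; aromatic-class areas are reported separately and
    never enter the denominator.  Components matching no window are
    collected as ``unassigned`` with a warning.
    """
    structural: dict[str, float] = {}
    aromatic: dict[str, float] = {}
    unassigned: list[PeakComponent] = []
    for c in d.components:
        e = scheme.assign(c)
        if e is None:
            unassigned.append(c)
        elif e.kind == "aromatic":
            aromatic[e.label] = aromatic.get(e.label, 0.0) + c.area
        else:
            structural[e.label] = structural.get(e.label, 0.0) + c.area
    if unassigned:
        centers = [round(c.center, 1) for c in unassigned]
        warnings.warn(f"unassigned components at {centers}", UnassignedComponentWarning, stacklevel=2)
    return StructureReport(
        fractions=_fractions_from_areas(structural),
        aromatic_areas=aromatic,
        unassigned=unassigned,
        scheme_name=scheme.name,
    )


def quantify_ss_conformers(
    d: DecompositionResult, scheme: AssignmentScheme = SS_CONFORMER_SCHEME
) -> ConformerReport:
    """Disulfide conformer fractions from a 500-550 cm^-1 decomposition.

    A class may own several sub-bands (the trans classes typically split in
    two); member areas are summed before normalizing to percent.
    """
    groups: dict[str, float] = {}
    members: dict[str, list[float]] = {}
    for c in d.components:
        e = scheme.assign(c)
        if e is None:
            warnings.warn(
                f"component at {c.center:.1f} cm^-1 outside all conformer windows",
                UnassignedComponentWarning,
                stacklevel=2,
            )
            continue
        groups[e.label] = groups.get(e.label, 0.0) + c.area
        members.setdefault(e.label, []).append(c.center)
    return ConformerReport(fractions=_fractions_from_areas(groups), member_bands=members)


def _local_max_height(s: Spectrum, center: float, half_width: float = 6.0) -> tuple[float, float]:
    """(position, height) of the local maximum nearest ``center`` within the window."""
    lo, hi = center - half_width, center + half_width
    mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
    if mask.sum() < 3:
        raise ValueError(f"window {center}±{half_width} cm^-1 not covered")
    x, y = s.wavenumber[mask], s.intensity[mask]
    (peaks,) = argrelmax(y)
    if peaks.size == 0:
        raise ValueError(f"no local maximum within {center}±{half_width} cm^-1")
    i = peaks[np.argmin(np.abs(x[peaks] - center))]
    return float(x[i]), float(y[i])


def tyrosine_doublet_ratio(s: Spectrum, half_width: float = 6.0) -> MarkerReport:
    """Tyrosine Fermi doublet height ratio I(855)/I(835) and its category.

    Expects a baseline-corrected spectrum covering 820-870 cm^-1.  Below
    0.9 the ratio is out of the calibrated range; 0.9-1.43 indicates Tyr
    acting as both hydrogen-bond donor and acceptor; above 1.43 as a
    positive-charge acceptor; ratios >= 2.0 additionally flag exposed
    anionic (Tyr-O-) residues.
    """
    _, h835 = _local_max_height(s, 835.0, half_width)
    _, h855 = _local_max_height(s, 855.0, half_width)
    if h835 <= 0:
        raise ValueError("835 cm^-1 peak height non-positive; baseline-correct first")
    ratio = h855 / h835
    if ratio < TYR_LOWER:
        category = "below_range"
    elif ratio <= TYR_UPPER:
        category = "donor_acceptor"
    else:
        category = "positive_charge_acceptor"
    return MarkerReport(
        tyr_ratio=ratio,
        tyr_category=category,
        tyr_exposed_anionic=bool(ratio >= TYR_EXPOSED),
    )


def tryptophan_intensity(s: Spectrum, half_width: float = 6.0) -> float:
    """Height of the Trp indole band at ~760 cm^-1 on the normalized scale.

    The spectrum must already be normalized to the 1460 cm^-1 reference
    band so heights are comparable across samples.
    """
    _, h = _local_max_height(s, 760.0, half_width)
    return h


def detect_marker_bands(s: Spectrum, catalog: list | None = None, rel_threshold: float = 0.01) -> list[dict]:
    """Presence, position and height for each catalog marker band.

    ``catalog`` entries are ``(center, (lo, hi), label)``.  A band is
    present when a local maximum exists in its window with height above
    ``rel_threshold`` of the spectrum maximum; shoulders (no strict local
    maximum but an inflection, i.e. a second-derivative minimum) are
    flagged ``shoulder``.  Absence is a valid result, never an error.
    """
    catalog = MARKER_CATALOG if catalog is None else catalog
    out = []
    top = float(np.abs(s.intensity).max())
    from .preprocess import resample_uniform, second_derivative

    work = resample_uniform(s)
    win = max(5, int(2 * round(2.0 / work.step) + 1))
    d2 = second_derivative(work, smooth_window=min(win, len(work) - (1 - len(work) % 2)))
    for center, (lo, hi), label in catalog:
        row = {"label": label, "expected_center": center, "present": False,
               "center": None, "height": None, "shoulder": False}
        mask = (s.wavenumber >= lo) & (s.wavenumber <= hi)
        if mask.sum() >= 3:
            try:
                pos, h = _local_max_height(s, center, (hi - lo) / 2)
                if h > rel_threshold * top:
                    row.update(present=True, center=pos, height=h)
            except ValueError:
                # shoulder: local minimum of the second derivative in-window
                m2 = (d2.wavenumber >= lo) & (d2.wavenumber <= hi)
                if m2.sum() >= 3:
                    (mins,) = argrelmax(-d2.intensity[m2])
                    if mins.size:
                        xw = d2.wavenumber[m2]
                        i = mins[np.argmin(np.abs(xw[mins] - center))]
                        h = float(np.interp(xw[i], s.wavenumber, s.intensity))
                        if h > rel_threshold * top:
                            row.update(present=True, center=float(xw[i]), height=h, shoulder=True)
        out.append(row)
    return out


def feature_vector(
    structure: StructureReport | None = None,
    conformers: ConformerReport | None = None,
    markers: MarkerReport | None = None,
) -> dict[str, float]:
    """Flat per-sample feature map (fractions + conformers + markers).

    This is the row exported to the feature-matrix CSV consumed by any
    external ordination/heat-map tool.
    """
    row: dict[str, float] = {}
    if structure is not None:
        row.update({f"frac_{k}": v for k, v in structure.fractions.items()})
        row.update({f"area_{k}": v for k, v in structure.aromatic_areas.items()})
    if conformers is not None:
        row.update({f"ss_{k}": v for k, v in conformers.fractions.items()})
    if markers is not None:
        if markers.tyr_ratio is not None:
            row["tyr_ratio"] = markers.tyr_ratio
        if markers.trp_intensity is not None:
            row["trp_760"] = markers.trp_intensity
    return row
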