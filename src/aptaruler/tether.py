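"""Composite worm-like-chain model of the aptamer tether.

The sensor tethers an 80-nm gold nanoparticle (AuNP) to a gold nanofilm
(AuNF) through a single 66-nt ssDNA aptamer plus short chemical linkers.
The tether is coarse-grained as a composite worm-like chain: flexible
ssDNA stretches are freely jointed chains of Kuhn-length links, while the
surface linkers and the folded aptamer–endotoxin complex are single rigid
rods.  Monte Carlo sampling of chain conformations under half-space
boundary conditions yields the equilibrium distribution of the gap z
between the particle attachment point and the film (film at z = 0).

Conventions
-----------
* z is the gap between the film surface and the tether's particle-side
  end, i.e. the chain end-to-end z-extension.  The particle is assumed
  attached at its lowest pole and its rotation is ignored, so the
  sphere-does-not-penetrate-the-film condition coincides with z >= 0.
* Every chain node (joint between links) must satisfy z >= 0; rejected
  conformations are resampled so an ensemble always holds exactly
  ``n_chains`` values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RD1_SEQUENCE",
    "SegmentSpec",
    "TetherSpec",
    "ParticleSpec",
    "PositionEnsemble",
    "ZSummary",
    "build_tether_spec",
    "sample_chain_conformations",
    "summarize_z",
]

#: 66-nt endotoxin aptamer construct: a 36-nt endotoxin-binding core
#: flanked by two 15-nt non-complementary extension arms.
RD1_SEQUENCE = (
    "AAGAAACAGTGAGGA"
    "GTCGAATGCTCTGCCTGGAAGAGTTGTTAGCAGGGA"
    "ACAGGAAAGAGTGGT"
)

#: Length of the endotoxin-binding core (nt).
BINDING_REGION_LENGTH = 36

# Coarse-grained geometry defaults.  ssDNA rise and Kuhn length are taken
# from the single-stranded DNA polymer-physics literature (rise ~0.6-0.7
# nm/nt; Kuhn length, i.e. twice the persistence length, ~1.5-3 nm at
# moderate ionic strength); within those ranges the values below are
# calibrated once so the unbound/bound ensemble means land on the
# experimental tether heights (about 7.1 and 5.4 nm).  The rigid end
# linker lumps the HSC11EG6 self-assembled monolayer arm, the amide
# coupling and the amino-C6 spacer on the film side, and the thiol anchor
# on the particle side.
DEFAULT_SSDNA_RISE = 0.63  # nm per nucleotide
DEFAULT_SSDNA_KUHN = 2.6  # nm
DEFAULT_LINKER_CONTOUR = 2.5  # nm, each end

_ENDOTOXIN_LENGTH_RANGE = (2.0, 4.0)  # nm, allowed rigid-complex sizes

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of the composite chain."""

    label: str
    contour_length: float  # nm
    kuhn_length: float  # nm; ignored for rigid segments
    rigid: bool = False

    def __post_init__(self) -> None:
        if self.contour_length <= 0:
            raise ValueError(f"segment {self.label!r}: contour_length must be > 0")
        if self.kuhn_length <= 0:
            raise ValueError(f"segment {self.label!r}: kuhn_length must be > 0")

    def link_lengths(self) -> np.ndarray:
        """Decompose the segment into freely jointed link lengths (nm).

        Rigid segments are a single rod.  Flexible segments are split
        into full Kuhn links plus one remainder link so the contour
        length is preserved exactly.
        """
        if self.rigid:
            return np.array([self.contour_length])
        n_full = int(self.contour_length // self.kuhn_length)
        rem = self.contour_length - n_full * self.kuhn_length
        links = [self.kuhn_length] * n_full
        if rem > 1e-9:
            links.append(rem)
        return np.asarray(links)


@dataclass(frozen=True)
class TetherSpec:
    """Ordered segments describing the full film-to-particle tether."""

    segments: tuple[SegmentSpec, ...]
    state: str  # "unbound" | "bound"
    sequence: str
    endotoxin_length: float | None = None  # nm, bound state only

    @property
    def total_contour(self) -> float:
        return float(sum(s.contour_length for s in self.segments))

    def link_lengths(self) -> np.ndarray:
        return np.concatenate([s.link_lengths() for s in self.segments])

    def spec_hash(self) -> str:
        payload = json.dumps(
            {
                "segments": [
                    (s.label, s.contour_length, s.kuhn_length, s.rigid)
                    for s in self.segments
                ],
                "state": self.state,
                "sequence": self.sequence,
                "endotoxin_length": self.endotoxin_length,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ParticleSpec:
    """Tethered nanoparticle (defaults: 80-nm gold sphere)."""

    diameter: float = 80.0  # nm
    material_label: str = "Au"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("particle diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class PositionEnsemble:
    """Monte Carlo sample of particle–film gaps z (nm)."""

    z_values: np.ndarray
    n_chains: int
    seed: int
    spec_hash: str

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)


@dataclass
class ZSummary:
    mean: float
    sd: float
    bin_centers: np.ndarray  # nm
    density: np.ndarray  # probability density, integrates to 1
    bin_width: float


def build_tether_spec(
    sequence: str = RD1_SEQUENCE,
    linker_contour: float = DEFAULT_LINKER_CONTOUR,
    ssdna_rise: float = DEFAULT_SSDNA_RISE,
    ssdna_kuhn: float = DEFAULT_SSDNA_KUHN,
    state: str = "unbound",
    endotoxin_length: float | None = None,
    binding_region_length: int = BINDING_REGION_LENGTH,
) -> TetherSpec:
    """Build the composite-chain description of the tether.

    Unbound state: ``[rigid linker, ssDNA(full sequence), rigid linker]``.
    Bound state: the central binding region folds around the endotoxin
    into a single rigid "complex" rod of length ``endotoxin_length``
    (2–4 nm), leaving the two flanking arms flexible:
    ``[linker, ssDNA(left arm), complex, ssDNA(right arm), linker]``.

    Parameters
    ----------
    sequence
        IUPAC A/C/G/T aptamer sequence (the shipped construct is 66 nt).
    linker_contour
        Rigid surface-linker contour length at each end, nm.  Zero
        disables the linkers.
    ssdna_rise, ssdna_kuhn
        ssDNA contour rise per nucleotide and Kuhn length, nm.
    state
        ``"unbound"`` or ``"bound"``.
    endotoxin_length
        Rigid complex size in nm, required for the bound state.  The
        degenerate case ``endotoxin_length=0`` with
        ``binding_region_length=0`` reduces to the unbound geometry.
    binding_region_length
        Number of central nucleotides that fold into the complex.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"unknown base(s) in sequence: {sorted(bad)}")
    if state not in ("unbound", "bound"):
        raise ValueError(f"state must be 'unbound' or 'bound', got {state!r}")

    def _linkers() -> tuple[SegmentSpec | None, SegmentSpec | None]:
        if linker_contour > 0:
            mk = lambda lab: SegmentSpec(lab, linker_contour, linker_contour, rigid=True)
            return mk("film_linker"), mk("particle_linker")
        return None, None

    film_link, particle_link = _linkers()

    if state == "unbound":
        segs = [
            film_link,
            SegmentSpec("ssDNA", len(sequence) * ssdna_rise, ssdna_kuhn),
            particle_link,
        ]
        return TetherSpec(tuple(s for s in segs if s), "unbound", sequence)

    # bound state
    if binding_region_length == 0:
        # Degenerate fold: nothing collapses, geometry equals unbound.
        if endotoxin_length not in (None, 0, 0.0):
            raise ValueError("empty binding region cannot host a finite complex")
        segs = [
            film_link,
            SegmentSpec("ssDNA", len(sequence) * ssdna_rise, ssdna_kuhn),
            particle_link,
        ]
        return TetherSpec(tuple(s for s in segs if s), "bound", sequence, 0.0)

    if binding_region_length > len(sequence):
        raise ValueError("binding region longer than sequence")
    if endotoxin_length is None:
        raise ValueError("bound state requires endotoxin_length")
    lo, hi = _ENDOTOXIN_LENGTH_RANGE
    if not lo <= endotoxin_length <= hi:
        raise ValueError(
            f"endotoxin_length {endotoxin_length} nm outside the modelled "
            f"complex-size range [{lo}, {hi}] nm"
        )

    n_flank = len(sequence) - binding_region_length
    n_left = n_flank // 2
    n_right = n_flank - n_left
    segs = [
        film_link,
        SegmentSpec("ssDNA_left", n_left * ssdna_rise, ssdna_kuhn) if n_left else None,
        SegmentSpec("complex", float(endotoxin_length), float(endotoxin_length), rigid=True),
        SegmentSpec("ssDNA_right", n_right * ssdna_rise, ssdna_kuhn) if n_right else None,
        particle_link,
    ]
    return TetherSpec(
        tuple(s for s in segs if s), "bound", sequence, float(endotoxin_length)
    )


def sample_chain_conformations(
    spec: TetherSpec,
    particle: ParticleSpec | None = None,
    n_chains: int = 100_000,
    seed: int | None = None,
    batch_size: int = 200_000,
    max_rejection_rate: float = 0.999,
) -> PositionEnsemble:
    """Monte Carlo sample of equilibrium tether extensions.

    Each chain is a freely jointed walk: every link (Kuhn segment or
    rigid rod) takes an independent orientation uniform on the sphere,
    so its z-step is uniform on ``[-L, L]``.  A conformation is accepted
    only if every chain node stays at or above the film (z >= 0), which
    also guarantees the particle sphere attached at the chain end does
    not penetrate the film.  Rejected conformations are resampled until
    exactly ``n_chains`` survive.

    Only the z-components are generated: the in-plane walk is isotropic
    and decouples from every constraint and observable used here.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    lengths = spec.link_lengths()
    if lengths.size == 0:
        raise ValueError("tether has no links (contour shorter than one Kuhn link)")

    rng = np.random.default_rng(seed)
    collected: list[np.ndarray] = []
    n_got = 0
    n_proposed = 0
    while n_got < n_chains:
        m = min(batch_size, max(4 * (n_chains - n_got), 1024))
        steps = rng.uniform(-1.0, 1.0, size=(m, lengths.size)) * lengths
        nodes = np.cumsum(steps, axis=1)
        ok = (nodes >= 0.0).all(axis=1)
        z_end = nodes[ok, -1]
        collected.append(z_end)
        n_got += z_end.size
        n_proposed += m
        if n_proposed >= 50 * n_chains and n_got / n_proposed < 1.0 - max_rejection_rate:
            raise RuntimeError(
                f"rejection rate {1 - n_got / n_proposed:.4%} exceeds "
                f"{max_rejection_rate:.1%}; the boundary conditions leave "
                "almost no allowed conformations for this tether"
            )
    z = np.concatenate(collected)[:n_chains]
    return PositionEnsemble(
        z_values=z, n_chains=n_chains, seed=seed, spec_hash=spec.spec_hash()
    )


def summarize_z(
    ensemble: PositionEnsemble | np.ndarray, bin_width: float = 0.25
) -> ZSummary:
    """Moments and normalized histogram of the gap distribution."""
    z = ensemble.z_values if isinstance(ensemble, PositionEnsemble) else np.asarray(ensemble, float)
    if z.size == 0:
        raise ValueError("empty ensemble")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    hi = max(float(z.max()), bin_width)
    n_bins = int(np.ceil(hi / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    density, edges = np.histogram(z, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ZSummary(
        mean=float(z.mean()),
        sd=float(z.std()),
        bin_centers=centers,
        density=density,
        bin_width=bin_width,
    )
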