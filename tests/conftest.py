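"""Shared fixtures: analytic and cohort-scale synthetic plaque geometries."""

import math

import numpy as np
import pytest

from plaqrecon.geometry import Contour, CrossSection
from plaqrecon.synthetic import NCSpec, PlaqueSpec, PopulationSpec, \
    make_idealized, sample_population


def circle(r, n=256, center=(0.0, 0.0), component="lumen"):
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    return Contour(pts, component)


def annular_sector(r_in, r_out, a0, a1, n=64, component="nc"):
    """Exact annular-sector polygon (radial edges, circular arcs)."""
    t = np.linspace(a0, a1, n)
    inner = np.column_stack([r_in * np.cos(t), r_in * np.sin(t)])
    outer = np.column_stack([r_out * np.cos(t), r_out * np.sin(t)])[::-1]
    return Contour(np.vstack([inner, outer]), component)


@pytest.fixture(scope="session")
def concentric_section():
    """Concentric rings: lumen 1.5, NC 2.0-2.5 over +/-30 deg, media at 3.0."""
    nc = annular_sector(2.0, 2.5, math.radians(60), math.radians(120), n=128)
    return CrossSection(
        section_id="concentric",
        artery_id="A",
        patient_id="P",
        lumen=circle(1.5, component="lumen"),
        intima_outer=circle(2.8, component="intima"),
        media_outer=circle(3.0, component="media"),
        adventitia_outer=circle(3.3, component="adventitia"),
        ncs=(nc,),
    )


@pytest.fixture(scope="session")
def concentric_spec():
    return PlaqueSpec(
        lumen_radius=1.5,
        far_imt=1.5,
        media_thickness=0.2,
        ncs=(NCSpec(nc_angle=math.radians(60), capt=(0.5, 0.5),
                    nct=(0.5, 0.5), imt=(1.5, 1.5)),),
    )


@pytest.fixture(scope="session")
def median_plaque():
    """Idealized plaque at the cohort median feature values."""
    return make_idealized(PlaqueSpec())


@pytest.fixture(scope="session")
def cohort():
    """Mid-size synthetic cohort reused by calibration tests."""
    pop = PopulationSpec(seed=42, n_patients=25, arteries_per_patient=2,
                         sections_per_artery=5)
    sections, truth = sample_population(pop)
    return sections, truth
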