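"""Shared fixtures: phantom scenarios exercised by several test modules.

Phantoms are generated programmatically (no stored volumes); the heavier
ones are session-scoped so unit, correction and acceptance tests share a
single rasterization.
"""

import numpy as np
import pytest

from seegseg import (
    HemispherePlane,
    PhantomElectrode,
    PhantomSpec,
    SegmentationConfig,
    default_model,
    make_phantom,
    straight_implant_spec,
)
from seegseg.phantom import electrode_geometry

S_DEFAULT = 1600.0


@pytest.fixture(scope="session")
def seg_config():
    return SegmentationConfig(threshold=S_DEFAULT)


@pytest.fixture(scope="session")
def straight_case():
    """Standard 10-electrode straight implant (tilted shafts)."""
    spec = straight_implant_spec(seed=1)
    vol, truth = make_phantom(spec)
    return {"spec": spec, "vol": vol, "truth": truth}


@pytest.fixture(scope="session")
def aligned_case():
    """Straight implant with all shafts exactly along +x (no tilt)."""
    spec = straight_implant_spec(seed=3, tilt_deg=0.0)
    vol, truth = make_phantom(spec)
    return {"spec": spec, "vol": vol, "truth": truth}


@pytest.fixture(scope="session")
def curved_case():
    """Single 12-contact shaft with a 10 degree mid-shaft bend."""
    model = default_model(12)
    entry = np.array([3.0, 25.0, 40.0])
    target = entry + (3.0 + 2.0 + 11 * 3.5) * np.array([1.0, 0.0, 0.0])
    elec = PhantomElectrode("K", entry=entry, target=target, model=model,
                            bend_angle=10.0, bend_fraction=0.5)
    spec = PhantomSpec(shape=(140, 140, 100), electrodes=[elec], seed=2)
    vol, truth = make_phantom(spec)
    return {"spec": spec, "vol": vol, "truth": truth}


@pytest.fixture(scope="session")
def crossing_case():
    """Straight shaft A crossed by a convergent two-shaft bundle.

    Shafts B and C cross A at 35 degrees, passing 1.7 and 2.9 mm from
    A's sixth contact: the metal-artifact blur merges their masses with
    A's contact into one blob that drags an unconstrained centroid more
    than 1 mm off A's axis.
    """
    m_a = default_model(12)
    entry = np.array([3.0, 45.0, 40.0])
    target = entry + (3.0 + 2.0 + 11 * 3.5) * np.array([1.0, 0.0, 0.0])
    a = PhantomElectrode("A", entry=entry, target=target, model=m_a)
    centers, _, _, _ = electrode_geometry(a)
    theta = np.radians(35.0)
    u_b = np.array([np.cos(theta), -np.sin(theta), 0.0])
    electrodes = [a]
    for label, offset in (("B", 1.7), ("C", 2.9)):
        cross_pt = centers[5] + np.array([0.0, offset, 0.0])
        t_b = cross_pt - (1.0 + 4 * 3.5) * u_b
        e_b = t_b + (3.0 + 2.0 + 9 * 3.5) * u_b
        electrodes.append(PhantomElectrode(label, entry=e_b, target=t_b,
                                           model=default_model(10)))
    spec = PhantomSpec(shape=(160, 200, 100), electrodes=electrodes, seed=5)
    vol, truth = make_phantom(spec)
    return {"spec": spec, "vol": vol, "truth": truth,
            "crossing_contact_index": 5}


@pytest.fixture(scope="session")
def bilateral_case():
    """Two collinear 8-contact shafts approaching from opposite sides,
    tips 1 mm apart across the x = 36 midplane."""
    model = default_model(8)
    left = PhantomElectrode("L", entry=np.array([6.0, 40.0, 40.0]),
                            target=np.array([35.5, 40.0, 40.0]), model=model)
    right = PhantomElectrode("R", entry=np.array([66.0, 40.0, 40.0]),
                             target=np.array([36.5, 40.0, 40.0]), model=model)
    spec = PhantomSpec(shape=(180, 140, 100), electrodes=[left, right], seed=9)
    vol, truth = make_phantom(spec)
    plane = HemispherePlane(point=np.array([36.0, 0.0, 0.0]),
                            normal=np.array([1.0, 0.0, 0.0]))
    return {"spec": spec, "vol": vol, "truth": truth, "plane": plane}


@pytest.fixture(scope="session")
def mixed_case():
    """One implant combining a straight shaft, a curved shaft, a crossing
    pair (2.8 mm clearance) and a bilateral collinear pair."""
    m8, m12 = default_model(8), default_model(12)
    electrodes = [
        PhantomElectrode("S", entry=np.array([3.0, 20.0, 30.0]),
                         target=np.array([3.0, 20.0, 30.0]) +
                         (3.0 + 2.0 + 7 * 3.5) * np.array([1.0, 0.0, 0.0]),
                         model=m8),
        PhantomElectrode("K", entry=np.array([20.0, 3.0, 44.0]),
                         target=np.array([20.0, 3.0, 44.0]) +
                         (3.0 + 2.0 + 11 * 3.5) * np.array([0.0, 1.0, 0.0]),
                         model=m12, bend_angle=10.0, bend_fraction=0.5),
        PhantomElectrode("A", entry=np.array([25.0, 3.0, 60.0]),
                         target=np.array([25.0, 3.0, 60.0]) +
                         (3.0 + 2.0 + 11 * 3.5) * np.array([0.0, 1.0, 0.0]),
                         model=m12),
    ]
    theta = np.radians(35.0)
    u_b = np.array([-np.sin(theta), np.cos(theta), 0.0])
    cross_pt = np.array([25.0 - 2.8, 28.0, 60.0])
    t_b = cross_pt - (1.0 + 4 * 3.5 + 1.75) * u_b
    electrodes.append(PhantomElectrode("B", entry=t_b + (3.0 + 2.0 + 9 * 3.5) * u_b,
                                       target=t_b, model=default_model(10)))
    m_bilat = default_model(8)
    electrodes.append(PhantomElectrode("L", entry=np.array([4.0, 60.0, 70.0]),
                                       target=np.array([33.5, 60.0, 70.0]),
                                       model=m_bilat))
    electrodes.append(PhantomElectrode("R", entry=np.array([64.0, 60.0, 70.0]),
                                       target=np.array([34.5, 60.0, 70.0]),
                                       model=m_bilat))
    spec = PhantomSpec(shape=(180, 200, 100), electrodes=electrodes, seed=11)
    vol, truth = make_phantom(spec)
    plane = HemispherePlane(point=np.array([34.0, 0.0, 0.0]),
                            normal=np.array([1.0, 0.0, 0.0]))
    return {"spec": spec, "vol": vol, "truth": truth, "plane": plane}
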