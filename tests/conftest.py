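import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinemorph.spine import Spine, Vertebra, make_labels

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_vertebra(label, centre, angle_deg=0.0, half_width=0.35, offset=0.2):
    """A vertebra at ``centre`` with horizontal endplates; the superior one is
    rotated by ``angle_deg`` in the sagittal plane."""
    centre = np.asarray(centre, dtype=float)
    e_inf = np.array([1.0, 0.0, 0.0])
    theta = np.radians(angle_deg)
    e_sup = np.array([np.cos(theta), np.sin(theta), 0.0])
    sup_mid = centre + np.array([0.0, offset, 0.0])
    inf_mid = centre - np.array([0.0, offset, 0.0])
    return Vertebra(
        label=label,
        centre=centre,
        superior_endplate=np.stack([sup_mid - half_width * e_sup,
                                    sup_mid + half_width * e_sup]),
        inferior_endplate=np.stack([inf_mid - half_width * e_inf,
                                    inf_mid + half_width * e_inf]),
    )


def make_straight_spine(specimen_id="straight", spacing=0.5, wedge_angles=None,
                        group="control", stage=9):
    """A perfectly straight vertical spine over the full C1..L7 layout."""
    wedge_angles = wedge_angles or {}
    vertebrae = []
    for i, label in enumerate(make_labels()):
        vertebrae.append(
            make_vertebra(
                label,
                centre=(0.0, -spacing * i, 0.0),
                angle_deg=wedge_angles.get(label, 0.0),
                half_width=0.7 * spacing,
                offset=0.4 * spacing,
            )
        )
    return Spine(specimen_id=specimen_id, stage=stage, group=group,
                 vertebrae=vertebrae)


@pytest.fixture
def straight_spine():
    return make_straight_spine()
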