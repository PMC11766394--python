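import numpy as np
import pytest

from zincbias import find_zinc_sites, parse_structure
from zincbias.synth_data import SiteSpec, make_zinc_site


@pytest.fixture
def ideal_site():
    """Jitter-free tetrahedral 3-donor zinc site (2 His NE2 + 1 Asp OD1)."""
    pdb, manifest = make_zinc_site(SiteSpec(seed=1))
    structure = parse_structure(pdb)
    sites = find_zinc_sites(structure)
    assert len(sites) == 1
    return sites[0], manifest


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
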