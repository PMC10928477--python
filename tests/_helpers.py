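"""Shared test scaffolding: trivial-geometry transport contexts."""

import numpy as np

from spinesim.distance_field import DistanceField, LatticeGrid
from spinesim.params import RepulsivePotentialParams
from spinesim.reaction_transport import InfluxGeometry, TransportContext

POT = RepulsivePotentialParams()


def uniform_ctx(grid, params, stimulus_on=False, geom=None, f_u=None,
                direction=None):
    """Transport context over a trivial geometry: flat direction field,
    zero confinement, every point active."""
    n = grid.n_points
    if direction is None:
        direction = np.tile([1.0, 0.0, 0.0], (n, 1))
    dfield = DistanceField(
        grid=grid, ds=-np.ones(n), face_id=np.zeros(n, dtype=np.int64),
        bary=np.zeros((n, 3)), direction=direction, w=np.zeros((n, 3)),
    )
    if geom is None:
        geom = InfluxGeometry(
            basal_mask=np.zeros(n, dtype=bool),
            stimulus_mask=np.zeros(n, dtype=bool),
            n_basal=1,
        )
        geom.basal_mask[0] = True
        geom.stimulus_mask[-1] = True
    return TransportContext(
        grid=grid, dfield=dfield, geom=geom, params=params, pot=POT,
        stimulus_on=stimulus_on, z_abs=-10.0,
        div_d=np.zeros(n), f_u=f_u if f_u is not None else np.zeros((n, 3)),
        div_fu=np.zeros(n), active=np.ones(n, dtype=bool),
    )
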