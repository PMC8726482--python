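"""Two-channel ddPCR droplet-count simulation.

Template molecules partition into droplets independently, so the number of
copies per droplet is Poisson with mean λ and a droplet is positive with
probability 1 − e^(−λ). Each channel (one per allele) draws its positive
count from the corresponding binomial, independently of the other channel.
"""

from __future__ import annotations

import numpy as np

from ..ddpcr import DdpcrWell
from ..params import DdpcrSimParams


def simulate_ddpcr_well(params: DdpcrSimParams, well_id: str = "A01") -> DdpcrWell:
    """Draw one well's positive-droplet counts for both allele channels."""
    rng = np.random.default_rng(params.seed)
    p_K = 1.0 - np.exp(-params.lambda_K)
    p_T = 1.0 - np.exp(-params.lambda_T)
    return DdpcrWell(
        well_id=well_id,
        n_partitions=params.n_partitions,
        n_pos_K=int(rng.binomial(params.n_partitions, p_K)),
        n_pos_T=int(rng.binomial(params.n_partitions, p_T)),
    )
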