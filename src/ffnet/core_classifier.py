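"""Three-criterion classifier for core flavor-contributing microbes.

A microbe is nominated as a core flavor contributor when it

1. is detected (relative abundance above the detection threshold) in *every*
   sample — stability across the whole fermentation;
2. participates in at least one strong association (an incident edge with
   |rho| above the correlation threshold); and
3. is connected to strictly more than ``min_connections`` volatiles in the
   significant bipartite network (default 35).

Criterion 2 is automatically satisfied by any connected node of a thresholded
network; it is still evaluated and reported for transparency. The rule applies
symmetrically to bacteria and fungi.
"""

from __future__ import annotations

import dataclasses

from .association_network import AssociationNetwork
from .errors import ValidationError
from .tabular_io import AbundanceTable


@dataclasses.dataclass
class CoreTaxonReport:
    """Per-microbe verdict of the three-criterion rule."""

    microbe_id: str
    present_in_all_samples: bool
    max_abs_rho: float
    n_connected_volatiles: int
    is_core: bool
    failing_criteria: list[int]
    connection_ratio: float  # degree / number of volatiles in the universe


def classify_core(
    network: AssociationNetwork,
    microbes: AbundanceTable,
    min_connections: int = 35,
    n_volatile_universe: int | None = None,
    detection_epsilon: float = 0.0,
    rho_threshold: float = 0.6,
) -> list[CoreTaxonReport]:
    """Apply the three-criterion rule to every microbe in the table.

    The report covers all microbes, including those absent from the network
    (degree 0). Raises if the network contains a microbe the table does not.
    """
    if not network.bipartite:
        raise ValidationError("core classification requires a bipartite network")
    table_ids = set(microbes.feature_ids)
    net_microbes = {
        n for n, d in network.graph.nodes(data=True) if d.get("role") == "microbe"
    }
    unknown = net_microbes - table_ids
    if unknown:
        raise ValidationError(
            f"network microbes absent from the abundance table: {sorted(unknown)}"
        )
    if n_volatile_universe is None:
        n_volatile_universe = len(
            [n for n, d in network.graph.nodes(data=True) if d.get("role") == "volatile"]
        )

    reports = []
    for mid in microbes.feature_ids:
        present = bool((microbes.data.loc[mid] > detection_epsilon).all())
        if mid in network.graph:
            incident = [
                abs(d["rho"]) for _, _, d in network.graph.edges(mid, data=True)
            ]
            degree = network.graph.degree(mid)
            max_abs_rho = max(incident) if incident else 0.0
        else:
            degree = 0
            max_abs_rho = 0.0

        failing = []
        if not present:
            failing.append(1)
        if not max_abs_rho > rho_threshold:
            failing.append(2)
        if not degree > min_connections:
            failing.append(3)

        reports.append(
            CoreTaxonReport(
                microbe_id=mid,
                present_in_all_samples=present,
                max_abs_rho=max_abs_rho,
                n_connected_volatiles=degree,
                is_core=not failing,
                failing_criteria=failing,
                connection_ratio=(
                    degree / n_volatile_universe if n_volatile_universe else 0.0
                ),
            )
        )
    return reports
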