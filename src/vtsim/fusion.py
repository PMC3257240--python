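"""SNARE-mediated docking and fusion between vesicle agents.

The effective number of SNARE pairs between two apposed membranes is the
strength-weighted sum over species combinations of the minimum of the two
local counts (there cannot be more pairs than the smaller number of
partners).  Local counts are the membrane totals scaled to the contact
patch, a spherical cap of height equal to the interaction layer; the
smaller patch governs.  The fusion rate constant is the per-pair constant
times the pair count; the fusion (docking) time is the per-pair time over
the pair count.  A vesicle whose coat shell is not fully depolymerized is
shielded and always bounces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .config import InteractionTables
from .vesicle import VesicleAgent, sphere_surface


@dataclass
class FusionCandidate:
    vesicle_ids: tuple[int, int]
    n_pairs: float
    k_fus: float
    t_fus: float
    docked_since: float = 0.0


def local_snare_counts(vesicle: VesicleAgent, patch_area: float) -> dict[str, float]:
    """Membrane-total SNARE counts scaled to the contact patch."""
    area = max(vesicle.surface, sphere_surface(vesicle.radius))
    frac = min(patch_area / area, 1.0)
    return {sp: n * frac for sp, n in vesicle.counts["snare"].items()}


def snare_pairs_from_counts(counts_i: dict[str, float], counts_j: dict[str, float],
                            tables: InteractionTables) -> float:
    """n_pairs = sum_uv s_uv * min(n_u_i, n_v_j) over all SNARE combinations."""
    total = 0.0
    for u, n_u in counts_i.items():
        if n_u <= 0:
            continue
        for v, n_v in counts_j.items():
            s = tables.snare_s(u, v)
            if s > 0 and n_v > 0:
                total += s * min(n_u, n_v)
    return total


def contact_patch_area(r_i: float, r_j: float, layer: float) -> float:
    """Interaction area: spherical cap of height ``layer`` on each partner;
    the smaller patch governs."""
    return 2.0 * math.pi * min(r_i, r_j) * layer


def snare_pairs(vesicle_i: VesicleAgent, vesicle_j: VesicleAgent,
                tables: InteractionTables, layer: float) -> float:
    """Effective SNARE pair count between two vesicles in contact."""
    a_int = contact_patch_area(vesicle_i.radius, vesicle_j.radius, layer)
    return snare_pairs_from_counts(local_snare_counts(vesicle_i, a_int),
                                   local_snare_counts(vesicle_j, a_int),
                                   tables)


def fusion_rate(n_pairs: float, k_fus_pair: float, tau_pair: float
                ) -> tuple[float, float]:
    """(k_fus, t_fus): rate scales with, time inversely with, the pair count."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if n_pairs == 0:
        return 0.0, math.inf
    return k_fus_pair * n_pairs, tau_pair / n_pairs


def fusion_allowed(mobile: VesicleAgent) -> bool:
    """Coat shielding: fusion only once the coat is fully depolymerized."""
    return mobile.n_pol == 0 and mobile.budding is None


def merge_vesicles(survivor: VesicleAgent, absorbed: VesicleAgent) -> VesicleAgent:
    """Merge ``absorbed`` into ``survivor`` conserving volume, surface, counts.

    The surviving identity is the larger partner's; callers should pass the
    larger partner as ``survivor``.
    """
    survivor.volume += absorbed.volume
    survivor.surface += absorbed.surface
    for group, d in absorbed.counts.items():
        for sp, n in d.items():
            survivor.add(group, sp, n)
    absorbed.counts = {g: {} for g in absorbed.counts}
    return survivor


def classify_fusion(vesicle: VesicleAgent, target: VesicleAgent) -> str:
    """'backward' iff the vesicle returns to the compartment it budded from."""
    if vesicle.donor_id is not None and target.id == vesicle.donor_id:
        return "backward"
    return "forward"
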