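"""Residual streams: processing by-products, food-waste pools, sludge, compost.

Processing splits a primary commodity into a main food product and by-products
via technical conversion factors (TCFs); by-products can be fed or used as
soil amendment. Of consumption waste, 35% is assumed recoverable as wet feed
for monogastric animals and fish (never ruminants, never across borders); the
remainder is compostable. Sewage sludge contributes fertilizer nutrients at
its current agricultural use rate (36%) with fixed N and P contents (7.5% and
1.2% of usable fresh mass).
"""

from __future__ import annotations

from typing import Mapping

from .instance import ResidualParams


def byproducts_from_processing(
    primary_t: float,
    tcf_entry: Mapping[str, object],
) -> dict[str, float]:
    """Split a primary flow into main product and by-products by TCFs.

    ``tcf_entry`` holds ``main_fraction`` and a ``byproducts`` map of
    feed-item id -> mass fraction. Output masses are input x fraction; the
    fractions must sum to at most 1, so mass out never exceeds mass in (the
    complement is processing loss).
    """
    if primary_t < 0:
        raise ValueError("primary flow must be >= 0")
    main = float(tcf_entry.get("main_fraction", 0.0))
    bps: Mapping[str, float] = tcf_entry.get("byproducts", {})  # type: ignore[assignment]
    total = main + sum(float(f) for f in bps.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"TCF fractions sum to {total:.6g} > 1")
    out = {"main": primary_t * main}
    for bpid, frac in bps.items():
        out[bpid] = primary_t * float(frac)
    return out


def waste_feed_allocation(
    consumption_waste_t: float,
    params: ResidualParams,
) -> tuple[float, float]:
    """(feed-eligible t, compost-eligible t) of a consumption-waste pool.

    The feed-eligible share (default 35%) is a wet feed usable only by
    monogastric animals and fish, and only in the country where the waste
    arises; the remainder is available for composting.
    """
    if consumption_waste_t < 0:
        raise ValueError("waste must be >= 0")
    feed = consumption_waste_t * params.waste_to_feed_frac
    return feed, consumption_waste_t - feed


def sludge_fertilizer(
    sludge_fresh_t: float,
    params: ResidualParams,
    already_usable: bool = False,
) -> dict[str, float]:
    """Usable sludge mass and its fertilizer N and P (t).

    ``usable = use_frac x fresh`` (36% of produced sludge reaches fields);
    N and P are fixed fractions (7.5% / 1.2%) of the usable mass. Pass
    ``already_usable=True`` when the input is the applied (post-36%) amount,
    the convention used for the baseline's reported sludge figure.
    """
    if sludge_fresh_t < 0:
        raise ValueError("sludge mass must be >= 0")
    usable = sludge_fresh_t if already_usable else sludge_fresh_t * params.sludge_use_frac
    return {
        "usable_t": usable,
        "n_t": usable * params.sludge_n_frac,
        "p_t": usable * params.sludge_p_frac,
    }


def compost_nutrients(
    waste_n_t: float,
    waste_p_t: float,
    params: ResidualParams,
) -> dict[str, float]:
    """N and P reaching the soil from composted waste.

    N passes through minus the gaseous loss fraction incurred during
    composting; P is conserved exactly (no gaseous P pathway).
    """
    if waste_n_t < 0 or waste_p_t < 0:
        raise ValueError("waste nutrient contents must be >= 0")
    return {
        "n_t": waste_n_t * (1.0 - params.compost_n_loss_frac),
        "p_t": waste_p_t,
    }
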