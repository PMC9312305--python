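"""Figures: mapping curves and sorted dose profiles.

Thin matplotlib layer over the mapping and metrics objects; every function
returns the Axes so callers can restyle or save.
"""

from __future__ import annotations

import numpy as np

from .mapping import MappingPolynomial
from .metrics import sorted_profile


def plot_mapping(poly: MappingPolynomial, ax=None, n: int = 200):
    """One quintic mapping curve over its valid domain (doses in cGy)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(*poly.valid_domain, n)
    ax.plot(x * 100.0, poly.evaluate_gy(x) * 100.0)
    src, tgt = (("5 mm depth", "surface") if poly.direction == "to_surface"
                else ("surface", "5 mm depth"))
    ax.set_xlabel(f"{src} dose (cGy)")
    ax.set_ylabel(f"{tgt} dose (cGy)")
    ax.set_title(f"{poly.cylinder_diameter:g} cm cylinder, {src} → {tgt}")
    return ax


def plot_sorted_profiles(solution, rx_by_site: dict, ax=None):
    """Fig-style sorted (highest to lowest) normalized dose profiles of one
    plan, one curve per site."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for site, rx in rx_by_site.items():
        prof = sorted_profile(solution.doses(site), rx)
        ax.plot(prof, label=f"{site} (Rx {rx:g} cGy)")
    ax.set_xlabel("point rank (hot → cold)")
    ax.set_ylabel("dose (% of site prescription)")
    ax.axhline(100.0, color="k", lw=0.5, ls="--")
    ax.legend()
    return ax
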