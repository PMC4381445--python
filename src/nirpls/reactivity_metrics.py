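"""Sugar release and carbohydrate yield arithmetic with anhydro correction.

A dilute-acid pretreatment plus enzymatic-hydrolysis assay liberates glucose
and xylose from a milled feedstock sample.  *Release* is the mass of
monomeric sugar per gram of dry biomass (g/g).  *Yield* expresses release as
a fraction of the theoretical maximum: the monomer mass is converted back to
its anhydro (polymer) equivalent — glucose x 162.14/180.16 to glucan, xylose
x 132.11/150.13 to xylan — and divided by the structural-carbohydrate mass
fraction of the feedstock.  Free sucrose contributes its glucosyl moiety to
the glucan basis (x 162.14/342.30); its fructose half is not tracked.

The combined GX quantities pool both sugars: GX release is the plain sum of
the two releases, while GX yield is the pooled ratio of summed
anhydro-corrected releases over summed carbohydrate bases, which keeps it a
fraction in [0, ~1] rather than a sum of two fractions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ANHYDRO_GLUCOSE",
    "ANHYDRO_XYLOSE",
    "GLUCOSYL_FROM_SUCROSE",
    "release_per_gram",
    "glucan_yield",
    "xylan_yield",
    "combined_sums",
    "reactivity_table",
    "REACTIVITY_COLUMNS",
]

# monomer-minus-water over monomer molar masses
ANHYDRO_GLUCOSE = 162.14 / 180.16   # glucose -> glucan
ANHYDRO_XYLOSE = 132.11 / 150.13    # xylose -> xylan
GLUCOSYL_FROM_SUCROSE = 162.14 / 342.30  # glucosyl anhydro unit per g sucrose

REACTIVITY_COLUMNS = (
    "G.Release", "X.Release", "GX.Release", "G.Yield", "X.Yield", "GX.Yield",
)


def release_per_gram(mass_released, dry_mass):
    """Grams of sugar released per gram of dry biomass loaded in the assay."""
    mass_released = np.asarray(mass_released, dtype=float)
    dry_mass = np.asarray(dry_mass, dtype=float)
    if np.any(dry_mass <= 0):
        raise ValueError("dry_mass must be > 0")
    if np.any(mass_released < 0):
        raise ValueError("mass_released must be >= 0")
    out = mass_released / dry_mass
    return float(out) if out.ndim == 0 else out


def _glucan_basis(glucan_frac, sucrose_frac):
    return np.asarray(glucan_frac, dtype=float) + np.asarray(sucrose_frac, dtype=float) * GLUCOSYL_FROM_SUCROSE


def glucan_yield(glucose_release, glucan_frac, sucrose_frac=0.0):
    """Anhydro-corrected glucose release over the glucan(+sucrose) basis."""
    basis = _glucan_basis(glucan_frac, sucrose_frac)
    if np.any(basis <= 0):
        raise ValueError("glucan + sucrose basis must be > 0")
    out = np.asarray(glucose_release, dtype=float) * ANHYDRO_GLUCOSE / basis
    return float(out) if out.ndim == 0 else out


def xylan_yield(xylose_release, xylan_frac):
    """Anhydro-corrected xylose release over the xylan mass fraction."""
    xylan_frac = np.asarray(xylan_frac, dtype=float)
    if np.any(xylan_frac <= 0):
        raise ValueError("xylan fraction must be > 0")
    out = np.asarray(xylose_release, dtype=float) * ANHYDRO_XYLOSE / xylan_frac
    return float(out) if out.ndim == 0 else out


def combined_sums(glucose_release, xylose_release, glucan_frac, xylan_frac,
                  sucrose_frac=0.0):
    """GX release (plain sum) and pooled GX yield.

    The pooled yield is (corrected glucose + corrected xylose release) over
    (glucan-equivalent + xylan bases); when both component yields equal y the
    pooled value is also y.
    """
    g = np.asarray(glucose_release, dtype=float)
    x = np.asarray(xylose_release, dtype=float)
    basis = _glucan_basis(glucan_frac, sucrose_frac) + np.asarray(xylan_frac, dtype=float)
    if np.any(basis <= 0):
        raise ValueError("total carbohydrate basis must be > 0")
    gx_release = g + x
    gx_yield = (g * ANHYDRO_GLUCOSE + x * ANHYDRO_XYLOSE) / basis
    if gx_release.ndim == 0:
        return float(gx_release), float(gx_yield)
    return gx_release, gx_yield


def reactivity_table(glucose_release, xylose_release, glucan_frac, xylan_frac,
                     sucrose_frac=0.0):
    """All six release/yield constituents as a name -> array mapping.

    Fractions are mass fractions of dry biomass (wt%/100); releases in g/g.
    """
    g = np.asarray(glucose_release, dtype=float)
    x = np.asarray(xylose_release, dtype=float)
    gx_release, gx_yield = combined_sums(g, x, glucan_frac, xylan_frac, sucrose_frac)
    return {
        "G.Release": g,
        "X.Release": x,
        "GX.Release": gx_release,
        "G.Yield": glucan_yield(g, glucan_frac, sucrose_frac),
        "X.Yield": xylan_yield(x, xylan_frac),
        "GX.Yield": gx_yield,
    }
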