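"""Published reference fixtures: feature-wavelength sets and CARS-MLR models.

The original kiwifruit study this package's workflow follows reported,
for each physicochemical index, the feature wavelengths selected by CARS
and SPA and the final CARS-MLR regression equations (coefficients in
physical units per unit SNV reflectance).  The raw fruit data behind
them were never deposited, so the exact selections are not recomputable;
they are shipped here verbatim as fixtures for demonstration and for
arithmetic self-checks.  Coefficients are stored to the printed decimal
precision only, so predictions from these models are approximate to
that precision.
"""

from __future__ import annotations

import numpy as np

from .grid import WavelengthGrid, default_grid
from .models import CalibratedModel
from .synthetic import INDEX_NAMES, INDEX_UNITS

#: reference feature-wavelength sets (nm), per index and selector
PUBLISHED_WAVELENGTHS: dict[str, dict[str, tuple[int, ...]]] = {
    "SSC": {
        "CARS": (393, 400, 407, 428, 430, 432, 439, 446, 453, 460, 600, 614,
                 878, 883, 891, 899, 904, 907, 920, 922, 925, 938, 941, 946,
                 948, 956, 959, 972, 988, 993, 996, 1012),
        "SPA": (428, 432, 439, 446, 458, 580, 614, 656, 1017, 1025),
    },
    "firmness": {
        "CARS": (397, 402, 421, 432, 556, 590, 626, 824, 889, 904, 946, 954,
                 964, 972, 975, 985, 1009, 1012),
        "SPA": (393, 397, 400, 402, 404, 409, 411, 442),
    },
    "L*": {
        "CARS": (400, 402, 404, 428, 522, 592, 595, 597, 626, 629, 631, 634,
                 636, 639, 698, 715, 721, 814, 824, 928, 1006, 1009, 1017,
                 1020, 1022, 1028),
        "SPA": (393, 400, 402, 407, 411, 484, 525, 573, 653, 696, 711, 907,
                998),
    },
    "a*": {
        "CARS": (402, 423, 430, 435, 453, 458, 489, 597, 617, 624, 626, 666,
                 683, 746, 789, 791, 794, 822, 827, 855, 904, 920, 956, 975,
                 977, 983, 998, 1001, 1004),
        "SPA": (407, 458, 520, 556, 678, 706, 852, 876, 964),
    },
    "b*": {
        "CARS": (411, 416, 418, 423, 430, 439, 449, 463, 520, 551, 553, 592,
                 595, 597, 617, 619, 622, 624, 626, 646, 746, 768, 786, 804,
                 806, 922, 951, 969, 988, 996, 1020, 1022),
        "SPA": (411, 421, 425, 449, 522, 549, 590, 619, 863, 870, 938, 964,
                1017, 1028),
    },
}

#: published CARS-MLR equations: intercept and {wavelength nm: coefficient}
PUBLISHED_MODELS: dict[str, tuple[float, dict[int, float]]] = {
    "SSC": (-142.2, {
        393: -62.4, 400: 111.4, 407: -75.9, 428: 146.5, 430: 75.9,
        432: -214.4, 439: 179.3, 446: -188.1, 453: -192.8, 460: 152.2,
        600: 42.4, 614: -99.5, 878: 57.8, 883: 253.8, 891: -230.9,
        899: -134.0, 904: -64.9, 907: -186.6, 920: 169.5, 922: -19.2,
        925: 307.6, 938: -147.5, 941: 227.0, 946: -265.4, 948: -205.0,
        956: 416.7, 959: 21.7, 972: -203.8, 988: 96.1, 993: -70.4,
        996: -18.7, 1012: 21.2,
    }),
    "firmness": (235.6, {
        397: 208.4, 402: -197.2, 421: -130.9, 432: 235.9, 556: 178.8,
        590: -234.1, 626: 203.0, 824: 51.2, 889: -161.2, 904: 131.2,
        946: 262.1, 954: -362.4, 964: -279.4, 972: 345.4, 975: 289.4,
        985: -236.1, 1009: 290.5, 1012: -301.8,
    }),
    "L*": (197.6, {
        400: -85.7, 402: 108.5, 404: 36.5, 428: -274.5, 522: -108.8,
        592: -254.2, 595: -1215.1, 597: 1922.1, 626: -216.1, 629: -262.9,
        631: 574.0, 634: -2265.0, 636: 2142.0, 639: -620.6, 698: 151.6,
        715: -171.4, 721: -22.6, 814: -143.8, 824: -58.6, 928: -190.2,
        1006: -39.5, 1009: -95.0, 1017: -31.1, 1020: -273.1, 1022: 184.8,
        1028: 137.5,
    }),
    "a*": (54.9, {
        402: 40.7, 423: -73.1, 430: -79.7, 435: 132.3, 453: -48.0,
        458: 192.8, 489: -114.3, 597: -290.3, 617: 626.3, 624: -309.5,
        626: -3.2, 666: 77.1, 683: -71.6, 746: 48.9, 789: 145.6,
        791: -13.8, 794: -293.5, 822: -14.8, 827: 245.2, 855: -132.5,
        904: 187.8, 920: -138.3, 956: -83.0, 975: 36.8, 977: 92.8,
        983: -29.6, 998: 81.8, 1001: 115.9, 1004: -214.9,
    }),
    "b*": (-29.1, {
        411: 60.6, 416: 90.9, 418: 130.2, 423: -10.0, 430: -269.5,
        439: -195.0, 449: 294.3, 463: 61.7, 520: -191.4, 551: 249.1,
        553: -67.2, 592: 697.0, 595: 207.6, 597: -1374.3, 617: -1011.1,
        619: 857.1, 622: 1120.6, 624: 754.0, 626: -1003.2, 646: -150.5,
        746: 191.1, 768: -424.8, 786: 287.9, 804: 590.7, 806: -526.7,
        922: 135.2, 951: -132.0, 969: 220.8, 988: -200.4, 996: 124.1,
        1020: 83.2, 1022: -90.0,
    }),
}


def _check_index(index: str) -> None:
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index '{index}'; expected one of "
                         f"{INDEX_NAMES}")


def load_published_wavelengths(index: str, method: str,
                               grid: WavelengthGrid | None = None,
                               tol_nm: float = 1.0) -> np.ndarray:
    """Reference wavelength list (nm) for one index and selector.

    The list is validated against ``grid`` (default axis if omitted):
    every wavelength must have a band center within ``tol_nm``.
    """
    _check_index(index)
    method = method.upper()
    if method not in ("CARS", "SPA"):
        raise ValueError(f"unknown method '{method}'; expected CARS or SPA")
    nm = np.array(PUBLISHED_WAVELENGTHS[index][method], dtype=float)
    grid = grid or default_grid()
    grid.indices_of(nm, tol=tol_nm)   # raises if any wavelength unresolvable
    return nm


def load_published_model(index: str,
                         grid: WavelengthGrid | None = None) -> CalibratedModel:
    """The published CARS-MLR model for one physicochemical index."""
    _check_index(index)
    intercept, terms = PUBLISHED_MODELS[index]
    nm = np.array(sorted(terms), dtype=float)
    coef = np.array([terms[int(w)] for w in nm], dtype=float)
    grid = grid or default_grid()
    grid.indices_of(nm, tol=1.0)
    return CalibratedModel(family="MLR", intercept=float(intercept),
                           coefficients=coef, wavelengths_nm=nm,
                           target=index, units=INDEX_UNITS[index])


def intercept_probe(model: CalibratedModel,
                    grid: WavelengthGrid | None = None) -> np.ndarray:
    """A full-grid spectrum that isolates a model's intercept.

    The returned vector is already standardized (mean 0, population sd 1,
    i.e. a fixed point of SNV) and carries exactly 0 at every wavelength
    the model reads, so ``predict(model, probe)`` returns the intercept.
    Useful for fixture self-checks and demonstrations.
    """
    grid = grid or default_grid()
    idx = grid.indices_of(model.wavelengths_nm, tol=1.0)
    rest = np.setdiff1d(np.arange(len(grid)), idx)
    v = np.zeros(len(grid))
    half = rest.size // 2
    if half == 0:
        raise ValueError("grid leaves no free bands for the probe")
    v[rest[:half]] = 1.0
    v[rest[half:2 * half]] = -1.0
    return v / v.std()


def wavelength_proportion_pct(n_selected: int, n_total: int = 256) -> float:
    """Share of selected wavelengths in the full axis, percent, 2 dp half-up."""
    from .evaluation import round_half_up
    return round_half_up(100.0 * n_selected / n_total, 2)
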