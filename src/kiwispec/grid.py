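"""Wavelength axis shared by all spectra and hypercubes.

The default axis models a 256-band visible/near-infrared imaging
spectrograph covering 390-1030 nm.  Real push-broom instruments have a
mildly nonlinear dispersion (the spectral sampling interval drifts across
the detector), so the default band centers are reconstructed by monotone
interpolation through the instrument's reported band centers rather than
by a uniform linspace; the average sampling interval is ~2.51 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator

N_BANDS_DEFAULT = 256
SPAN_DEFAULT = (390.0, 1030.0)

# (band index, nominal band center in nm) calibration anchors of the default
# instrument axis; between anchors the axis is filled by monotone (PCHIP)
# interpolation, pinned to the span endpoints.
_DISPERSION_ANCHORS: tuple[tuple[int, int], ...] = (
    (1, 393), (3, 397), (4, 400), (5, 402), (6, 404), (7, 407), (8, 409),
    (9, 411), (10, 416), (11, 418), (12, 421), (13, 423), (14, 425),
    (15, 428), (16, 430), (17, 432), (18, 435), (20, 439), (21, 442),
    (22, 446), (24, 449), (25, 453), (27, 458), (28, 460), (29, 463),
    (37, 484), (39, 489), (52, 520), (53, 522), (54, 525), (63, 549),
    (64, 551), (65, 553), (66, 556), (73, 573), (76, 580), (80, 590),
    (81, 592), (82, 595), (83, 597), (84, 600), (89, 614), (90, 617),
    (91, 619), (92, 622), (93, 624), (94, 626), (95, 629), (96, 631),
    (97, 634), (98, 636), (99, 639), (102, 646), (105, 653), (106, 656),
    (110, 666), (115, 678), (117, 683), (122, 696), (123, 698), (126, 706),
    (128, 711), (130, 715), (132, 721), (142, 746), (151, 768), (158, 786),
    (159, 789), (160, 791), (161, 794), (165, 804), (166, 806), (169, 814),
    (172, 822), (173, 824), (174, 827), (184, 852), (185, 855), (189, 863),
    (191, 870), (194, 876), (195, 878), (197, 883), (199, 889), (200, 891),
    (203, 899), (205, 904), (206, 907), (211, 920), (212, 922), (213, 925),
    (215, 928), (219, 938), (220, 941), (222, 946), (223, 948), (224, 951),
    (225, 954), (226, 956), (227, 959), (229, 964), (231, 969), (232, 972),
    (233, 975), (234, 977), (236, 983), (237, 985), (238, 988), (240, 993),
    (241, 996), (242, 998), (244, 1001), (245, 1004), (246, 1006),
    (247, 1009), (248, 1012), (250, 1017), (251, 1020), (252, 1022),
    (253, 1025), (254, 1028),
)


@lru_cache(maxsize=1)
def _default_wavelengths() -> np.ndarray:
    idx = [a[0] for a in _DISPERSION_ANCHORS]
    wav = [float(a[1]) for a in _DISPERSION_ANCHORS]
    if idx[0] != 0:
        idx = [0] + idx
        wav = [SPAN_DEFAULT[0]] + wav
    if idx[-1] != N_BANDS_DEFAULT - 1:
        idx = idx + [N_BANDS_DEFAULT - 1]
        wav = wav + [SPAN_DEFAULT[1]]
    axis = PchipInterpolator(np.asarray(idx), np.asarray(wav))(
        np.arange(N_BANDS_DEFAULT)
    )
    axis[0], axis[-1] = SPAN_DEFAULT
    axis.setflags(write=False)
    return axis


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing axis of band centers, in nanometers."""

    wavelengths: np.ndarray = field(default_factory=_default_wavelengths)

    def __post_init__(self) -> None:
        wav = np.asarray(self.wavelengths, dtype=float)
        if wav.ndim != 1 or wav.size < 2:
            raise ValueError("wavelength grid needs at least two bands")
        if not np.all(np.diff(wav) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wav)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def index_of(self, nm: float, tol: float | None = None) -> int:
        """Index of the band center nearest ``nm``.

        With ``tol`` set, raise if the nearest band center is farther than
        ``tol`` nanometers away.
        """
        i = int(np.argmin(np.abs(self.wavelengths - nm)))
        if tol is not None and abs(self.wavelengths[i] - nm) > tol:
            raise ValueError(
                f"grid has no band within {tol} nm of {nm} nm "
                f"(nearest is {self.wavelengths[i]:.2f} nm)"
            )
        return i

    def indices_of(self, nms, tol: float | None = None) -> np.ndarray:
        return np.array([self.index_of(x, tol=tol) for x in nms], dtype=int)

    def __eq__(self, other) -> bool:  # frozen dataclass + ndarray field
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and bool(np.allclose(self.wavelengths, other.wavelengths))
        )

    def __hash__(self) -> int:
        return hash((self.wavelengths.size,
                     float(self.wavelengths[0]), float(self.wavelengths[-1])))


def default_grid() -> WavelengthGrid:
    """The package-wide default 256-band 390-1030 nm axis."""
    return WavelengthGrid()
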