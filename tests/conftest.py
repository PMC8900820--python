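import numpy as np
import pytest

from polyclust import LaueGroup, ReflectionSet, UnitCell


@pytest.fixture(scope="session")
def laue_4mmm() -> LaueGroup:
    return LaueGroup.from_name("4/mmm")


@pytest.fixture(scope="session")
def laue_all() -> dict[str, LaueGroup]:
    return {name: LaueGroup.from_name(name) for name in ("-1", "2/m", "mmm", "4/mmm")}


@pytest.fixture(scope="session")
def small_cell() -> UnitCell:
    """Small tetragonal cell so ASU enumeration stays tiny."""
    return UnitCell(10.0, 10.0, 8.0)


def make_set(
    hkl,
    amplitude,
    sigma=None,
    cell: UnitCell | None = None,
    laue: LaueGroup | None = None,
    id: str = "test",
    dmin: float = 1.0,
    dmax: float = 50.0,
) -> ReflectionSet:
    """Convenience constructor for hand-written reflection sets."""
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    amplitude = np.asarray(amplitude, dtype=float)
    if sigma is None:
        sigma = np.ones(len(hkl))
    return ReflectionSet(
        id=id,
        cell=cell or UnitCell(10.0, 10.0, 8.0),
        laue=laue or LaueGroup.from_name("4/mmm"),
        hkl=hkl,
        amplitude=amplitude,
        sigma=np.asarray(sigma, dtype=float),
        dmin=dmin,
        dmax=dmax,
    )
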