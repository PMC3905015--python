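import numpy as np
import pytest

from pixelccs import FixtureSpec, RasterConfig, fixture_cloud


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.00, altloc=" ", element="C", record="ATOM") -> str:
    """Format one fixed-column PDB ATOM/HETATM line."""
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm:<4.4s}{altloc:1.1s}{resname:<3s} "
            f"{chain:1s}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


@pytest.fixture
def single_atom_pdb(tmp_path):
    path = tmp_path / "single.pdb"
    path.write_text(atom_line(1, "C", "UNK", "A", 1, 0, 0, 0) + "\nEND\n")
    return path


@pytest.fixture
def fine_raster():
    """High-resolution raster for analytic comparisons."""
    return RasterConfig(pixel_size=0.05, stride=1)


@pytest.fixture
def helix_cloud():
    """A small asymmetric cloud (helical arrangement of carbons)."""
    return fixture_cloud(FixtureSpec(kind="helix", count=12))


@pytest.fixture
def random_cloud():
    return fixture_cloud(FixtureSpec(kind="random_cloud", count=50, seed=3))
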