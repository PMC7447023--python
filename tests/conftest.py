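import pytest

from epinet.network import build_network


def network_with_values(values: dict[str, float]):
    """Genotype network from haplotype -> mean phenotype, one member per
    vertex (member phenotype equals the mean)."""
    vertices = {
        hap: {
            "members": [f"m_{hap}"],
            "member_phenotypes": [v],
            "mean_phenotype": float(v),
        }
        for hap, v in values.items()
    }
    return build_network(vertices, loci=[f"pos{k}" for k in range(len(next(iter(values))))])


@pytest.fixture
def square_network():
    """Single four-cycle over two biallelic positions."""
    return network_with_values({"AA": 0.0, "AT": 1.0, "TA": 1.0, "TT": 2.0})


@pytest.fixture
def reciprocal_square_network():
    """Both single mutants below the wild type; TT the unique maximum."""
    return network_with_values({"AA": 1.0, "AT": 0.0, "TA": 0.0, "TT": 2.0})


@pytest.fixture
def cube_network():
    """3-cube over {A,T}^3: 8 vertices, 12 edges, 6 squares."""
    haps = ["".join(p) for p in __import__("itertools").product("AT", repeat=3)]
    values = {h: float(h.count("T")) for h in haps}
    return network_with_values(values)

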