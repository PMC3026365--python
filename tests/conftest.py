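import dendropy
import pytest
from dendropy.calculate import treecompare
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Tabular BLAST output realizing the motivating example: three queries
#: A, B, C each returning subject 'a' as a hit, at differing ranks.
ABC_TABULAR = (
    "A\tother1\t99.0\t200\t2\t0\t1\t200\t1\t200\t1e-90\t350.0\n"
    "A\ta\t97.0\t200\t6\t0\t1\t200\t1\t200\t1e-80\t300.0\n"
    "B\ta\t98.0\t200\t4\t0\t1\t200\t1\t200\t1e-85\t320.0\n"
    "C\tother2\t99.5\t200\t1\t0\t1\t200\t1\t200\t1e-95\t360.0\n"
    "C\tother3\t98.5\t200\t3\t0\t1\t200\t1\t200\t1e-88\t340.0\n"
    "C\ta\t96.0\t200\t8\t0\t1\t200\t1\t200\t1e-70\t280.0\n"
)


@pytest.fixture
def abc_results():
    from assocnet.blast_io import parse_blast_tabular

    return parse_blast_tabular(ABC_TABULAR)


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance via dendropy (independent of the package)."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    tb = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)
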