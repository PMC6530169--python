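import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from taxonym import TaxonRecord, TaxonomyTable, build_index


def _rec(rid, name, status="accepted", accepted_id=None):
    return TaxonRecord(
        record_id=rid,
        canonical_name=name,
        raw_name=name,
        status=status,
        accepted_id=accepted_id or rid,
        kingdom="plantae",
        sources=frozenset({"test"}),
    )


@pytest.fixture
def oak_table():
    """Three accepted names plus one synonym of quercus alba."""
    return TaxonomyTable(records=[
        _rec("ub1", "quercus alba"),
        _rec("ub2", "quercus rubra"),
        _rec("ub3", "poa annua"),
        _rec("ub4", "quercus candida", status="synonym", accepted_id="ub1"),
    ])


@pytest.fixture
def oak_index(oak_table):
    return build_index(oak_table, n=3)


@pytest.fixture
def make_record():
    return _rec


@pytest.fixture
def dict_tsv(tmp_path):
    """Write dictionary rows to a TSV file and return its path."""

    def _write(rows, header=("record_id", "name", "status", "accepted_id",
                             "rank", "kingdom", "sources")):
        path = tmp_path / "dict.tsv"
        lines = ["\t".join(header)]
        lines += ["\t".join(str(c) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
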