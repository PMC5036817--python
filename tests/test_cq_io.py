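"""Long/wide panel parsing, sentinel handling, round-trips."""

import numpy as np
import pandas as pd
import pytest

from refstab import (
    generate,
    read_cq_long,
    read_cq_wide,
    write_cq_long,
    write_cq_wide,
    write_report,
    StabilityTable,
    SimulationConfig,
)
from refstab.cq_io import CqFormatError

LONG_HEADER = "sample,group,gene,replicate,cq\n"


def write(tmp_path, text, name="panel.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadLong:
    def test_undetermined_sentinel_becomes_missing(self, tmp_path):
        p = write(
            tmp_path,
            LONG_HEADER
            + "s1,a,g1,1,20.1\ns1,a,g1,2,Undetermined\ns2,a,g1,1,21.0\ns2,a,g1,2,21.2\n",
        )
        panel = read_cq_long(p)
        assert panel.n_genes == 1 and panel.n_samples == 2 and panel.n_replicates == 2
        assert panel.n_missing == 1
        assert np.isnan(panel.values[0, 0, 1])

    @pytest.mark.parametrize("sentinel", ["", "NA", "nan", "UNDETERMINED", "NaN"])
    def test_all_sentinel_spellings(self, tmp_path, sentinel):
        p = write(tmp_path, LONG_HEADER + f"s1,a,g1,1,{sentinel}\ns1,a,g1,2,20\n")
        assert read_cq_long(p).n_missing == 1

    def test_absent_rows_filled_as_missing(self, tmp_path):
        # (g2, s2, 2) never appears -> filled as missing
        p = write(
            tmp_path,
            LONG_HEADER
            + "s1,a,g1,1,20\ns1,a,g1,2,20\ns2,a,g1,1,20\ns2,a,g1,2,20\n"
            + "s1,a,g2,1,22\ns1,a,g2,2,22\ns2,a,g2,1,22\n",
        )
        panel = read_cq_long(p)
        assert panel.n_missing == 1
        gi, si = panel.genes.index("g2"), panel.samples.index("s2")
        assert np.isnan(panel.values[gi, si, 1])

    def test_duplicate_triple_names_the_triple(self, tmp_path):
        p = write(tmp_path, LONG_HEADER + "s1,a,g1,1,20\ns1,a,g1,1,21\n")
        with pytest.raises(CqFormatError, match=r"\('g1', 's1', '1'\)"):
            read_cq_long(p)

    def test_conflicting_group_labels_rejected(self, tmp_path):
        p = write(tmp_path, LONG_HEADER + "s1,a,g1,1,20\ns1,b,g1,2,20\n")
        with pytest.raises(CqFormatError, match="conflicting group"):
            read_cq_long(p)

    def test_non_numeric_cq_reports_line_number(self, tmp_path):
        p = write(tmp_path, LONG_HEADER + "s1,a,g1,1,20\ns1,a,g1,2,oops\n")
        with pytest.raises(CqFormatError, match="line 3"):
            read_cq_long(p)

    def test_row_order_does_not_matter(self, tmp_path, rng):
        rows = [
            f"s{j},grp,g{i},{r},{20 + i + 0.1 * r}"
            for i in range(3)
            for j in range(4)
            for r in (1, 2)
        ]
        a = read_cq_long(write(tmp_path, LONG_HEADER + "\n".join(rows), "a.csv"))
        rng.shuffle(rows)
        b = read_cq_long(write(tmp_path, LONG_HEADER + "\n".join(rows), "b.csv"))
        assert a == b


class TestReadWide:
    def test_wide_parse(self, tmp_path):
        w = write(tmp_path, "gene,s1.1,s1.2,s2.1,s2.2\ng1,20,20.2,21,NA\ng2,25,25,25,25\n")
        m = write(tmp_path, "sample,group\ns1,a\ns2,b\n", "meta.csv")
        panel = read_cq_wide(w, m)
        assert panel.n_reactions == 8 and panel.n_missing == 1
        assert panel.groups == {"s1": "a", "s2": "b"}

    def test_unparseable_header(self, tmp_path):
        w = write(tmp_path, "gene,s1_rep1\ng1,20\n")
        m = write(tmp_path, "sample,group\ns1,a\n", "meta.csv")
        with pytest.raises(CqFormatError, match="not parseable"):
            read_cq_wide(w, m)

    def test_sample_missing_from_metadata(self, tmp_path):
        w = write(tmp_path, "gene,s1.1,s2.1\ng1,20,21\n")
        m = write(tmp_path, "sample,group\ns1,a\n", "meta.csv")
        with pytest.raises(CqFormatError, match="s2"):
            read_cq_wide(w, m)


class TestRoundTrips:
    @pytest.fixture
    def panel(self):
        cfg = SimulationConfig(
            n_stable=2, n_unstable=2, n_regulated=1, n_per_group=(3, 3),
            n_replicates=3, seed=7,
        )
        panel, _ = generate(cfg)
        # knock out a reaction by hand to exercise NA round-tripping
        panel.values[0, 0, 0] = np.nan
        return panel

    def test_long_round_trip(self, tmp_path, panel):
        p = tmp_path / "rt.csv"
        write_cq_long(panel, p)
        once = read_cq_long(p)
        p2 = tmp_path / "rt2.csv"
        write_cq_long(once, p2)
        assert once == read_cq_long(p2)
        assert p.read_text() == p2.read_text()

    def test_wide_long_cross_round_trip(self, tmp_path, panel):
        lp = tmp_path / "long.csv"
        write_cq_long(panel, lp)
        long_panel = read_cq_long(lp)
        wp, mp = tmp_path / "wide.csv", tmp_path / "meta.csv"
        write_cq_wide(long_panel, wp, mp)
        assert read_cq_wide(wp, mp) == long_panel


class TestWriteReport:
    def test_stability_table_tsv_schema_and_round_trip(self, tmp_path):
        table = StabilityTable.from_scores(
            "demo", pd.Series({"g1": 0.2, "g2": 0.5, "g3": 0.1})
        )
        out = tmp_path / "table.tsv"
        write_report(table, out)
        back = pd.read_csv(out, sep="\t")
        assert list(back.columns) == ["gene", "score", "rank"]
        assert list(zip(back["gene"], back["rank"])) == [
            ("g3", 1.0), ("g1", 2.0), ("g2", 3.0),
        ]

    def test_nested_result_goes_to_json(self, tmp_path, rng):
        import json

        from refstab import rank_genorm
        from conftest import random_cq_matrix

        res = rank_genorm(random_cq_matrix(rng, 5, 8))
        out = tmp_path / "genorm.json"
        write_report(res, out)
        payload = json.loads(out.read_text())
        assert set(payload) >= {"ranking", "m_trace", "final_m", "v_curve"}
        assert len(payload["ranking"]) == 5
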