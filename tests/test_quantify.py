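"""Join/filter, unique-PSM selection, AUC aggregation, proportions."""

import math
import random

import pytest

from glycoquant.byonic_reader import IdentRow
from glycoquant.glycan_model import GlycanComposition, ModifiedPeptide
from glycoquant.quantify import (
    GlycoformKey,
    SiteAnchor,
    aggregate_auc,
    annotate_sites,
    build_occupancy_table,
    build_wide_table,
    compute_proportions,
    join_and_filter,
    select_unique_psms,
)

G0F = GlycanComposition({"HexNAc": 4, "Hex": 3, "Fuc": 1})
M3 = GlycanComposition({"HexNAc": 2, "Hex": 3})
EMPTY = GlycanComposition.empty()


def ident(
    seq="EEQYNSTYR",
    glycan=G0F,
    scan=100,
    score=350.0,
    calc_mz=1000.0,
    start=176,
    site_offset=5,
    master="P01857",
    sample="s1",
):
    mods = ((site_offset, round(glycan.mass, 4)),) if glycan is not None else ()
    glycans = [glycan] if glycan is not None else []
    return IdentRow(
        protein_name=f"sp|{master}|X_HUMAN",
        master_id=master,
        peptide=ModifiedPeptide(sequence=seq, mods=mods, start=start),
        glycan_text=str(glycan) if glycan is not None else "",
        glycans=glycans,
        score=score,
        scan=scan,
        calc_mz=calc_mz,
        source_file=sample,
    )


def records(*rows, sample="s1", score_cutoff=200.0):
    area_map = {r.scan: getattr(r, "_area") for r in rows}
    recs, _ = join_and_filter(rows, area_map, score_cutoff, sample=sample)
    return annotate_sites(recs)


def with_area(row, area):
    row._area = area
    return row


class TestJoinAndFilter:
    def test_area_joined_by_scan(self):
        row = ident(scan=10288, score=350)
        recs, stats = join_and_filter([row], {10288: 2e6}, 200.0, sample="s1")
        assert len(recs) == 1 and recs[0].area == 2e6
        assert stats.kept == 1

    def test_missing_area_row_dropped(self):
        recs, stats = join_and_filter([ident(scan=99999)], {10288: 2e6}, 200.0)
        assert recs == [] and stats.removed_no_area == 1

    def test_score_below_cutoff_dropped(self):
        recs, stats = join_and_filter([ident(score=150)], {100: 2e6}, 200.0)
        assert recs == [] and stats.removed_low_score == 1

    def test_raising_cutoff_is_monotone(self):
        rows = [ident(scan=i, score=s) for i, s in enumerate((50, 150, 250, 900), 1)]
        areas = {r.scan: 1e6 for r in rows}
        counts = [
            len(join_and_filter(rows, areas, cutoff)[0])
            for cutoff in (0, 200, 1000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSelectUniquePsms:
    def test_max_area_record_survives(self):
        a = with_area(ident(scan=1), 2e6)
        b = with_area(ident(scan=2), 5e5)
        unique = select_unique_psms(records(a, b), mode="site")
        assert [u.area for u in unique] == [2e6]

    def test_charge_states_have_distinct_keys(self):
        a = with_area(ident(scan=1, calc_mz=1000.0), 2e6)
        b = with_area(ident(scan=2, calc_mz=667.0), 1e6)
        unique = select_unique_psms(records(a, b), mode="site")
        assert len(unique) == 2

    def test_single_record_is_idempotent(self):
        recs = records(with_area(ident(scan=1), 2e6))
        once = select_unique_psms(recs, mode="site")
        assert select_unique_psms(once, mode="site") == once

    def test_tie_breaks_on_score_then_scan(self):
        a = with_area(ident(scan=5, score=300), 1e6)
        b = with_area(ident(scan=2, score=400), 1e6)
        unique = select_unique_psms(records(a, b), mode="site")
        assert unique[0].ident.scan == 2  # higher score wins the area tie
        c = with_area(ident(scan=9, score=400), 1e6)
        d = with_area(ident(scan=3, score=400), 1e6)
        unique = select_unique_psms(records(c, d), mode="site")
        assert unique[0].ident.scan == 3  # then lower scan

    def test_order_invariance(self):
        rows = [with_area(ident(scan=i, score=200 + i), 1e5 * i) for i in range(1, 8)]
        recs = records(*rows)
        baseline = select_unique_psms(recs, mode="site")
        rng = random.Random(7)
        for _ in range(5):
            shuffled = recs[:]
            rng.shuffle(shuffled)
            assert select_unique_psms(shuffled, mode="site") == baseline

    def test_peptide_mode_ignores_site_in_key(self):
        # same peptide/composition/m/z but glycan placed on different residues
        a = with_area(ident(scan=1, seq="NVSNVTK", site_offset=1, glycan=M3, start=10), 2e6)
        b = with_area(ident(scan=2, seq="NVSNVTK", site_offset=4, glycan=M3, start=10), 1e6)
        recs = records(a, b)
        assert len(select_unique_psms(recs, mode="site")) == 2
        assert len(select_unique_psms(recs, mode="peptide")) == 1


class TestAggregateAuc:
    def test_sums_across_charge_states(self):
        a = with_area(ident(scan=1, calc_mz=1000.0), 2e6)
        b = with_area(ident(scan=2, calc_mz=667.0), 1e6)
        auc = aggregate_auc(select_unique_psms(records(a, b), "site"), "site")
        anchor = SiteAnchor("P01857", 180, "N")
        assert auc[(GlycoformKey.make(anchor, G0F), "s1")] == pytest.approx(3e6)

    def test_single_psm_total(self):
        a = with_area(ident(scan=1), 5e5)
        auc = aggregate_auc(select_unique_psms(records(a), "site"), "site")
        assert list(auc.values()) == [5e5]

    def test_unglycosylated_peptide_anchors_to_spanned_glycosite(self):
        glyco = with_area(ident(scan=1), 2e6)
        unglyc = with_area(ident(scan=2, glycan=None, calc_mz=500.0), 1e6)
        auc = aggregate_auc(select_unique_psms(records(glyco, unglyc), "site"), "site")
        anchor = SiteAnchor("P01857", 180, "N")
        assert auc[(GlycoformKey.make(anchor, EMPTY), "s1")] == 1e6

    def test_missed_cleavage_variants_merge_in_site_mode_only(self):
        short = with_area(ident(scan=1, seq="EEQYNSTYR", start=176), 2e6)
        longer = with_area(
            ident(scan=2, seq="TKPREEQYNSTYR", start=172, site_offset=9, calc_mz=1400.0),
            1e6,
        )
        recs = records(short, longer)
        site_auc = aggregate_auc(select_unique_psms(recs, "site"), "site")
        assert len(site_auc) == 1 and list(site_auc.values()) == [3e6]
        pep_auc = aggregate_auc(select_unique_psms(recs, "peptide"), "peptide")
        assert len(pep_auc) == 2


class TestProportions:
    def _table(self, aucs, unglyc=None):
        anchor = SiteAnchor("P1", 100, "N")
        auc_map = {}
        for i, a in enumerate(aucs):
            comp = GlycanComposition({"HexNAc": 2 + i, "Hex": 3})
            auc_map[(GlycoformKey.make(anchor, comp), "s1")] = a
        if unglyc is not None:
            auc_map[(GlycoformKey.make(anchor, EMPTY), "s1")] = unglyc
        return compute_proportions(auc_map)

    def test_without_unglycosylated_signal(self):
        df = self._table([3e6, 1e6])
        glyc = df[df.composition != "Unglycosylated"]
        assert sorted(glyc.proportion_without_unglyc) == [0.25, 0.75]
        assert sorted(glyc.proportion_with_unglyc) == [0.25, 0.75]
        assert (df.occupancy == 1.0).all()

    def test_with_unglycosylated_signal(self):
        df = self._table([3e6, 1e6], unglyc=4e6)
        by_comp = df.set_index("composition")
        assert by_comp.loc["Unglycosylated", "proportion_with_unglyc"] == 0.5
        assert math.isnan(by_comp.loc["Unglycosylated", "proportion_without_unglyc"])
        glyc = df[df.composition != "Unglycosylated"]
        assert sorted(glyc.proportion_with_unglyc) == [0.125, 0.375]
        assert sorted(glyc.proportion_without_unglyc) == [0.25, 0.75]
        assert (df.occupancy == 0.5).all()

    def test_single_glycoform_is_unity_both_ways(self):
        df = self._table([5e6])
        assert df.proportion_with_unglyc.iloc[0] == 1.0
        assert df.proportion_without_unglyc.iloc[0] == 1.0

    def test_occupancy_complements_unglycosylated_with_proportion(self):
        df = self._table([2e6, 2e6], unglyc=1e6)
        u = df[df.composition == "Unglycosylated"].iloc[0]
        assert u.occupancy == pytest.approx(1.0 - u.proportion_with_unglyc, abs=1e-12)


class TestWideTable:
    def _long(self):
        anchor = SiteAnchor("P1", 100, "N")
        auc_map = {}
        for sample in ("s1", "s2"):
            auc_map[(GlycoformKey.make(anchor, M3), sample)] = 3e6
            auc_map[(GlycoformKey.make(anchor, G0F), sample)] = 1e6
        auc_map[(GlycoformKey.make(anchor, EMPTY), "s1")] = 4e6
        return compute_proportions(auc_map)

    def test_shape_and_blocks(self):
        wide = build_wide_table(self._long(), ["s1", "s2"], {"P1": "Protein one"})
        assert len(wide) == 3  # 2 glycoforms + unglycosylated
        numeric = [c for c in wide.columns if c.split("_")[-1] in ("s1", "s2")]
        assert len(numeric) == 6
        assert wide.protein_name.unique().tolist() == ["Protein one"]

    def test_unobserved_cells_blank_not_zero(self):
        wide = build_wide_table(self._long(), ["s1", "s2"])
        row = wide[wide.composition == "Unglycosylated"].iloc[0]
        assert math.isnan(row["auc_s2"])
        assert row["auc_s1"] == 4e6

    def test_empty_input_gives_header_only(self):
        import pandas as pd

        empty = compute_proportions({})
        wide = build_wide_table(empty, ["s1"])
        occ = build_occupancy_table(empty, ["s1"])
        assert len(wide) == 0 and "auc_s1" in wide.columns
        assert len(occ) == 0 and "occupancy_s1" in occ.columns

    def test_deterministic_row_order(self):
        long_df = self._long()
        a = build_wide_table(long_df, ["s1", "s2"])
        b = build_wide_table(long_df.sample(frac=1, random_state=3), ["s1", "s2"])
        assert a.equals(b)


class TestNormalizationInvariants:
    def test_proportions_sum_to_one_per_anchor_sample(self, site_result):
        for (anchor, sample), grp in site_result.long.groupby(
            ["anchor_label", "sample"]
        ):
            assert grp.proportion_with_unglyc.sum() == pytest.approx(1.0, abs=1e-9)
            without = grp.proportion_without_unglyc.dropna()
            if len(without):
                assert without.sum() == pytest.approx(1.0, abs=1e-9)

    def test_occupancy_bounds_and_edge(self, site_result):
        occ = site_result.long.occupancy
        assert ((occ >= 0) & (occ <= 1)).all()
        for (anchor, sample), grp in site_result.long.groupby(
            ["anchor_label", "sample"]
        ):
            has_unglyc = (grp.composition == "Unglycosylated").any()
            if not has_unglyc:
                assert (grp.occupancy == 1.0).all()
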