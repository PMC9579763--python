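"""Occurrence table reading, cleaning filters and summaries."""

import pytest

from palaeodiv.occurrences import (
    Determinacy,
    Environment,
    Material,
    dedupe_localities,
    filter_indeterminate,
    filter_material,
    read_occurrences,
    summarize,
    write_occurrences,
)

from conftest import make_dataset, make_record

COLUMN_MAP = {
    "occurrence_id": "id",
    "genus": "genus",
    "species": "species",
    "locality_id": "locality",
    "earliest_stage": "early_stage",
    "latest_stage": "late_stage",
    "age_max": "age_max",
    "age_min": "age_min",
    "environment": "env",
}


def write_csv(tmp_path, rows, header):
    path = tmp_path / "occ.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestRead:
    HEADER = "id,genus,species,locality,early_stage,late_stage,age_max,age_min,env"

    def test_identity_read_through(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "o1,Elonichthys,robisoni,L1,Serpukhovian,Serpukhovian,,,marine",
                "o2,Rhadinichthys,,L1,Serpukhovian,Serpukhovian,,,marine",
                "o3,Platysomus,parvulus,L2,Moscovian,Moscovian,,,freshwater",
            ],
            self.HEADER,
        )
        ds = read_occurrences(path, COLUMN_MAP)
        assert len(ds) == 3
        assert [r.occurrence_id for r in ds] == ["o1", "o2", "o3"]
        assert ds.records[1].determinacy is Determinacy.GENUS
        assert ds.records[2].environment is Environment.FRESHWATER

    def test_missing_locality_column_names_role(self, tmp_path):
        path = write_csv(
            tmp_path, ["o1,A,x,L1,S,S,,,m"], self.HEADER
        )
        bad_map = {k: v for k, v in COLUMN_MAP.items() if k != "locality_id"}
        with pytest.raises(ValueError, match="locality_id"):
            read_occurrences(path, bad_map)

    def test_missing_stratigraphy_names_role(self, tmp_path):
        path = write_csv(tmp_path, ["o1,A,x,L1,S,S,,,m"], self.HEADER)
        bad_map = {
            k: v for k, v in COLUMN_MAP.items()
            if k not in ("earliest_stage", "latest_stage", "age_max", "age_min")
        }
        with pytest.raises(ValueError, match="stratigraphy"):
            read_occurrences(path, bad_map)

    def test_inverted_age_range_strict_raises_citing_row(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "o1,A,x,L1,,,330.9,323.2,marine",
                "o2,B,y,L1,,,300.0,310.0,marine",
            ],
            self.HEADER,
        )
        with pytest.raises(ValueError, match="row 1"):
            read_occurrences(path, COLUMN_MAP, strict=True)

    def test_lenient_mode_drops_and_logs(self, tmp_path):
        path = write_csv(
            tmp_path,
            [
                "o1,A,x,L1,,,330.9,323.2,marine",
                "o2,B,y,L1,,,300.0,310.0,marine",
            ],
            self.HEADER,
        )
        ds = read_occurrences(path, COLUMN_MAP, strict=False)
        assert len(ds) == 1
        assert ds.cleaning_log[0].removed == 1

    def test_roundtrip(self, tmp_path):
        ds = make_dataset([make_record(), make_record(genus="Platysomus")])
        out = tmp_path / "round.csv"
        write_occurrences(ds, out)
        back = read_occurrences(
            out,
            {
                "occurrence_id": "occurrence_id", "genus": "genus",
                "species": "species", "determinacy": "determinacy",
                "material": "material", "locality_id": "locality_id",
                "earliest_stage": "earliest_stage",
                "latest_stage": "latest_stage", "environment": "environment",
            },
        )
        assert len(back) == 2
        assert back.records[1].genus == "Platysomus"


class TestFilters:
    def test_indeterminate_removed_at_genus_rank(self):
        ds = make_dataset(
            [
                make_record(),
                make_record(species=None),
                make_record(genus=None, species=None),
            ]
        )
        out = filter_indeterminate(ds, rank="genus")
        assert len(out) == 2
        assert out.cleaning_log[-1].removed == 1

    def test_genus_determinate_retained_at_species_rank(self):
        ds = make_dataset(
            [make_record(), make_record(species=None),
             make_record(genus=None, species=None)]
        )
        out = filter_indeterminate(ds, rank="species")
        assert {r.determinacy for r in out} == {
            Determinacy.SPECIES, Determinacy.GENUS
        }

    def test_all_determinate_is_identity(self):
        ds = make_dataset([make_record(), make_record(genus="Platysomus")])
        out = filter_indeterminate(ds, rank="genus")
        assert [r.occurrence_id for r in out] == [r.occurrence_id for r in ds]

    def test_empty_dataset_logs_zero(self):
        out = filter_indeterminate(make_dataset([]), rank="genus")
        assert len(out) == 0
        assert out.cleaning_log[-1].removed == 0

    def test_material_filter(self):
        ds = make_dataset(
            [
                make_record(material=Material.BODY),
                make_record(material=Material.SCALE),
                make_record(material=Material.TOOTH),
                make_record(material=Material.UNKNOWN),
            ]
        )
        out = filter_material(ds)
        assert [r.material for r in out] == [Material.BODY, Material.UNKNOWN]
        assert out.cleaning_log[-1].removed == 2
        assert "unknown material" in out.cleaning_log[-1].note

    def test_all_scales_removed_entirely(self):
        ds = make_dataset([make_record(material=Material.SCALE)] * 0 or [
            make_record(material=Material.SCALE) for _ in range(4)
        ])
        out = filter_material(ds)
        assert len(out) == 0
        assert out.cleaning_log[-1].removed == 4

    @pytest.mark.parametrize("filt", [
        lambda d: filter_material(d),
        lambda d: filter_indeterminate(d, "genus"),
    ])
    def test_filters_idempotent(self, filt):
        ds = make_dataset(
            [make_record(), make_record(material=Material.SCALE),
             make_record(genus=None, species=None)]
        )
        once = filt(ds)
        twice = filt(once)
        assert [r.occurrence_id for r in once] == [r.occurrence_id for r in twice]
        assert twice.cleaning_log[-1].removed == 0

    def test_filter_order_independence(self):
        ds = make_dataset(
            [make_record(), make_record(material=Material.TOOTH),
             make_record(genus=None, species=None),
             make_record(material=Material.SCALE, genus=None, species=None)]
        )
        a = filter_material(filter_indeterminate(ds, "genus"))
        b = filter_indeterminate(filter_material(ds), "genus")
        assert [r.occurrence_id for r in a] == [r.occurrence_id for r in b]

    def test_cleaning_log_reconciles_sizes(self):
        ds = make_dataset(
            [make_record(), make_record(material=Material.SCALE),
             make_record(genus=None, species=None)]
        )
        out = filter_material(filter_indeterminate(ds, "genus"))
        assert sum(e.removed for e in out.cleaning_log) == len(ds) - len(out)


class TestDedupe:
    def test_same_name_close_coords_merge(self):
        ds = make_dataset(
            [
                make_record(locality_id="a", locality_name="Glencartholm",
                            modern_lat=55.01, modern_lon=-3.0),
                make_record(locality_id="b", locality_name="Glencartholm",
                            modern_lat=55.012, modern_lon=-3.003),
            ]
        )
        _, n, _ = dedupe_localities(ds, "by-name-and-coords")
        assert n == 1

    def test_same_name_distant_coords_split(self):
        ds = make_dataset(
            [
                make_record(locality_id="a", locality_name="Bear Gulch",
                            modern_lat=46.0),
                make_record(locality_id="b", locality_name="Bear Gulch",
                            modern_lat=47.0),
            ]
        )
        _, n, _ = dedupe_localities(ds, "by-name-and-coords")
        assert n == 2

    def test_by_id_counts_ids_and_warns_on_conflict(self):
        ds = make_dataset(
            [
                make_record(locality_id="L1", modern_lat=10.0),
                make_record(locality_id="L1", modern_lat=12.0),
                make_record(locality_id="L2"),
            ]
        )
        _, n, warnings = dedupe_localities(ds, "by-id")
        assert n == 2
        assert len(warnings) == 1 and "L1" in warnings[0]


class TestSummarize:
    def test_direct_counts(self):
        ds = make_dataset(
            [
                make_record(genus="A", species="x", locality_id="L1"),
                make_record(genus="A", species="y", locality_id="L1"),
                make_record(genus="B", species="z", locality_id="L2"),
                make_record(genus="B", species="z", locality_id="L2"),
                make_record(genus="A", species="x", locality_id="L2"),
            ]
        )
        s = summarize(ds)
        assert (s.n_occurrences, s.n_species, s.n_genera, s.n_localities) == (
            5, 3, 2, 2
        )

    def test_indeterminate_excluded_from_taxon_tallies(self):
        ds = make_dataset(
            [make_record(genus="A", species="x"),
             make_record(genus=None, species=None)]
        )
        s = summarize(ds)
        assert (s.n_species, s.n_genera) == (1, 1)

    def test_empty(self):
        s = summarize(make_dataset([]))
        assert (s.n_occurrences, s.n_species, s.n_genera, s.n_localities) == (
            0, 0, 0, 0
        )
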