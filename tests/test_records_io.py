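"""CSV ingestion, dataset completion, round-trips, and entry tallies."""

from __future__ import annotations

import pytest

from extracteval.records_io import (
    AttributeKind,
    AttributeSpec,
    Dataset,
    ExtractionRecord,
    Source,
    default_registry,
    entry_table,
    read_extractions,
    round_half_up,
    tally_entries,
    write_extractions,
)


def _write(tmp_path, name, rows):
    path = tmp_path / name
    lines = ["article_id,attribute,value"] + [",".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestRegistry:
    def test_default_has_eleven_study_attributes(self, registry):
        assert len(registry) == 11
        kinds = {name: registry[name].kind for name in registry}
        assert kinds["latitude/longitude"] is AttributeKind.COORDINATE
        assert sum(1 for k in kinds.values() if k is AttributeKind.DATE) == 4
        # place names and Latin binomials are never stemmed
        assert not registry["study site"].stemmed
        assert not registry["focal species"].stemmed
        assert registry["ecosystem type"].stemmed

    def test_stemmed_flag_restricted_to_terms(self):
        with pytest.raises(ValueError):
            AttributeSpec("x", AttributeKind.DATE, stemmed=True)


class TestReadExtractions:
    def test_rows_merge_into_one_record(self, tmp_path, registry):
        path = _write(
            tmp_path, "m.csv",
            [("A1", "ecosystem type", "salt marsh"), ("A1", "ecosystem type", "lagoon")],
        )
        ds = read_extractions(path, Source.MANUAL, registry)
        rec = ds.cell("A1", "ecosystem type")
        assert rec.values == ("salt marsh", "lagoon")
        assert not rec.none_reported

    def test_none_reported_sentinel(self, tmp_path, registry):
        path = _write(tmp_path, "m.csv", [("A1", "latitude/longitude", "none reported")])
        rec = read_extractions(path, "manual", registry).cell("A1", "latitude/longitude")
        assert rec.none_reported and rec.values == ()

    def test_sentinel_is_case_insensitive(self, tmp_path, registry):
        path = _write(tmp_path, "m.csv", [("A1", "study site", "None Reported")])
        assert read_extractions(path, "manual", registry).cell("A1", "study site").none_reported

    def test_completion_gives_record_per_cell(self, tmp_path, registry):
        path = _write(tmp_path, "m.csv", [("A1", "study site", "Tampa Bay")])
        ds = read_extractions(path, "manual", registry)
        assert len(ds.records) == 11
        assert ds.cell("A1", "monitoring end date").none_reported
        assert ds.is_complete

    def test_unknown_attribute_names_the_row(self, tmp_path, registry):
        path = _write(tmp_path, "m.csv", [("A1", "colour", "blue")])
        with pytest.raises(ValueError, match="colour"):
            read_extractions(path, "manual", registry)

    def test_value_conflicting_with_sentinel_rejected(self, tmp_path, registry):
        path = _write(
            tmp_path, "m.csv",
            [("A1", "study site", "Tampa Bay"), ("A1", "study site", "none reported")],
        )
        with pytest.raises(ValueError, match="none reported"):
            read_extractions(path, "manual", registry)

    def test_row_order_does_not_matter(self, tmp_path, registry):
        rows = [
            ("A2", "study site", "Tampa Bay"),
            ("A1", "ecosystem type", "lagoon"),
            ("A1", "study site", "Puget Sound"),
        ]
        ds1 = read_extractions(_write(tmp_path, "a.csv", rows), "manual", registry)
        ds2 = read_extractions(_write(tmp_path, "b.csv", rows[::-1]), "manual", registry)
        assert ds1.records == ds2.records

    def test_surrounding_whitespace_stripped_internal_kept(self, tmp_path, registry):
        path = tmp_path / "m.csv"
        path.write_text(
            'article_id,attribute,value\nA1,study site,"  Elkhorn   Slough  "\n'
        )
        rec = read_extractions(path, "manual", registry).cell("A1", "study site")
        assert rec.values == ("Elkhorn   Slough",)


def test_read_write_round_trip(tmp_path, registry):
    rows = [
        ("A1", "ecosystem type", "salt marsh"),
        ("A1", "ecosystem type", "lagoon"),
        ("A2", "focal species", "Mya arenaria"),
        ("A2", "latitude/longitude", "none reported"),
    ]
    ds = read_extractions(_write(tmp_path, "m.csv", rows), "manual", registry)
    out = tmp_path / "round.csv"
    write_extractions(ds, out)
    again = read_extractions(out, "manual", registry)
    assert again.records == ds.records


def test_completion_never_alters_existing_records(tmp_path, registry):
    ds = read_extractions(
        _write(tmp_path, "m.csv", [("A1", "study site", "Tampa Bay")]),
        "manual", registry, complete=False,
    )
    before = dict(ds.records)
    completed = ds.complete(["A1", "A2"])
    for key, rec in before.items():
        assert completed.records[key] == rec
    assert len(completed.records) == 22


class TestTallies:
    def test_study_site_rates(self, registry):
        # 138 manual and 184 automated entries over 80 articles -> 1.7 / 2.3
        manual = Dataset(Source.MANUAL, registry)
        automated = Dataset(Source.AUTOMATED, registry)
        for i in range(80):
            art = f"A{i:02d}"
            n_m = 2 if i < 58 else 1            # 58*2 + 22*1 = 138
            n_a = 3 if i < 24 else 2            # 24*3 + 56*2 = 184
            manual.add(ExtractionRecord(
                art, "study site", Source.MANUAL, tuple(f"site {j}" for j in range(n_m))
            ))
            automated.add(ExtractionRecord(
                art, "study site", Source.AUTOMATED, tuple(f"site {j}" for j in range(n_a))
            ))
        manual, automated = manual.complete(), automated.complete()
        tm = tally_entries(manual).set_index("attribute")
        ta = tally_entries(automated).set_index("attribute")
        assert tm.loc["study site", "entries"] == 138
        assert tm.loc["study site", "rate_1dp"] == 1.7
        assert ta.loc["study site", "entries"] == 184
        assert ta.loc["study site", "rate_1dp"] == 2.3
        combined = entry_table(manual, automated).set_index("attribute")
        assert combined.loc["study site", "rate_difference"] == pytest.approx(0.6)

    def test_all_none_reported_counts_zero(self, registry):
        ds = Dataset(Source.MANUAL, registry)
        ds.add(ExtractionRecord("A1", "study site", Source.MANUAL, (), none_reported=True))
        ds = ds.complete()
        tally = tally_entries(ds)
        assert (tally["entries"] == 0).all()

    def test_tally_sums_match_total_value_count(self, tmp_path, registry):
        rows = [
            ("A1", "ecosystem type", "salt marsh"),
            ("A1", "focal species", "Mya arenaria"),
            ("A1", "focal species", "Zostera marina"),
            ("A2", "study site", "Tampa Bay"),
        ]
        ds = read_extractions(_write(tmp_path, "m.csv", rows), "manual", registry)
        assert tally_entries(ds)["entries"].sum() == ds.total_values()

    def test_empty_dataset_rejected(self, registry):
        with pytest.raises(ValueError):
            tally_entries(Dataset(Source.MANUAL, registry))


def test_record_invariant_enforced():
    with pytest.raises(ValueError):
        ExtractionRecord("A1", "study site", Source.MANUAL, ("x",), none_reported=True)


def test_round_half_up():
    assert round_half_up(78.75, 1) == 78.8
    assert round_half_up(62.5, 0) == 63.0
    assert round_half_up(0.05, 1) == 0.1
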