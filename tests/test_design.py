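"""Tandem-array promoter assembly: repeat arithmetic, spacer screening,
construct validation against an independent rescanner."""

import numpy as np
import pytest

from synprom.design import (
    DesignConfig,
    PromoterDesign,
    ScreeningLibrary,
    build_promoter,
    choose_spacers,
    repeat_count,
    validate_design,
)
from synprom.motifs import Pwm
from synprom.simulate import random_library

from test_scanning import naive_scan


def sharp_pwm(site: str, ident: str) -> Pwm:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    prob = np.full((len(site), 4), 0.01)
    for i, c in enumerate(site):
        prob[i, idx[c]] = 0.97
    return Pwm(ident, ident, prob / prob.sum(axis=1, keepdims=True))


class TestRepeatCount:
    def test_ten_bp_site_gives_twelve_repeats(self):
        assert repeat_count(10, 120) == 12

    def test_site_as_long_as_target_gives_one(self):
        assert repeat_count(120, 120) == 1

    def test_eight_bp_site_gives_fifteen(self):
        assert repeat_count(8, 120) == 15

    def test_half_up_tie_rounds_up(self):
        # 16 bp site: 120/16 = 7.5 -> 8 repeats
        assert repeat_count(16, 120) == 8

    def test_total_within_half_site_of_target_for_all_widths(self):
        for w in range(4, 41):
            r = repeat_count(w, 120)
            assert abs(r * w - 120) <= w / 2

    def test_narrow_site_rejected(self):
        with pytest.raises(ValueError):
            repeat_count(3, 120)


class TestChooseSpacers:
    def test_single_repeat_needs_no_spacer(self, library8):
        lib = ScreeningLibrary.from_pwms(library8)
        spacers, warnings = choose_spacers(
            "ACGTACGTAC", 1, lib, DesignConfig(), library8[0].id
        )
        assert spacers == [] and warnings == []

    def test_spacer_count_and_length(self, library8):
        cfg = DesignConfig()
        lib = ScreeningLibrary.from_pwms(library8)
        site = "CGGGGCATGC"
        spacers, _ = choose_spacers(site, 5, lib, cfg, library8[0].id)
        assert len(spacers) == 4
        assert all(len(s) == 3 for s in spacers)

    def test_spacer_avoids_recreating_other_motifs(self):
        """A decoy motif matching the site/AAA-spacer junction forces the
        first-fit search past 'AAA'; acceptance is decided by a full scan
        of the assembled array, not heuristics."""
        site = "TTTTTTTT"
        site_motif = sharp_pwm(site, "polyT")
        decoy = sharp_pwm("TTAAATTT", "decoy")  # spans a TTT|AAA|TTT junction
        lib = ScreeningLibrary.from_pwms([site_motif, decoy])
        spacers, warnings = choose_spacers(site, 3, lib, DesignConfig(), "polyT")
        assert warnings == []
        assert "AAA" not in spacers  # would assemble the decoy's site
        array = site + spacers[0] + site + spacers[1] + site
        sm = lib.matrices["decoy"]
        assert naive_scan(sm, array, lib.thresholds["decoy"]) == []
        # and the intended motif is present exactly once per repeat
        own = naive_scan(lib.matrices["polyT"], array, lib.thresholds["polyT"])
        assert len({off for off, _ in own}) == 3


class TestBuildPromoter:
    def test_layout_arithmetic_width_eight(self, library8):
        pwm = sharp_pwm("ACGTTGCA", "W8")
        d = build_promoter(pwm, list(library8))
        assert d.repeats == 15
        array_len = 15 * 8 + 14 * 3
        assert array_len == 162
        assert len(d.full_seq) == array_len + len(d.core_promoter_seq)

    def test_full_length_formula_across_widths(self):
        rng = np.random.default_rng(0)
        for w in (4, 9, 13, 22, 40):
            site = "".join(rng.choice(list("ACGT"), size=w))
            pwm = sharp_pwm(site, f"W{w}")
            d = build_promoter(pwm, [pwm])
            cfg = DesignConfig()
            expected = (
                d.repeats * w + (d.repeats - 1) * cfg.spacer_len
                + len(cfg.core_promoter_seq)
            )
            assert len(d.full_seq) == expected

    def test_deterministic(self, library8):
        a = build_promoter(library8[2], list(library8))
        b = build_promoter(library8[2], list(library8))
        assert a.full_seq == b.full_seq
        assert a.spacer_seqs == b.spacer_seqs

    def test_site_spans_carry_site_sequence(self, library8):
        d = build_promoter(library8[1], list(library8))
        for s, e in d.site_spans:
            assert d.full_seq[s:e] == d.site_seq

    def test_clean_design_validates(self, library8):
        d = build_promoter(library8[0], list(library8))
        assert d.intended_hits == d.repeats
        assert d.unintended_hits == 0
        assert d.warnings == []


class TestValidateDesign:
    def test_counts_agree_with_naive_scanner(self, library8):
        lib = ScreeningLibrary.from_pwms(library8)
        d = build_promoter(library8[3], list(library8))
        intended, unintended, per_motif = validate_design(d, lib)
        for mid, sm in lib.matrices.items():
            naive = naive_scan(sm, d.full_seq, lib.thresholds[mid])
            # one occurrence per window: dedupe strand pairs
            assert per_motif[mid] == len({off for off, _ in naive})

    def test_forced_bad_spacer_counts_unintended(self):
        site_motif = sharp_pwm("TTTTTTTT", "polyT")
        decoy = sharp_pwm("TTTTTTTT", "decoy")  # identical: every hit doubles
        lib = ScreeningLibrary.from_pwms([site_motif, decoy])
        d = PromoterDesign(
            tf_name="polyT", motif_id="polyT", site_seq="TTTTTTTT",
            repeats=2, spacer_seqs=["TTT"],
            core_promoter_seq="G" * 40, core_promoter_name="core",
        )
        intended, unintended, _ = validate_design(d, lib)
        assert unintended > 0

    def test_off_register_own_hits_are_unintended(self):
        pwm = sharp_pwm("TTTT", "T4")
        lib = ScreeningLibrary.from_pwms([pwm])
        d = PromoterDesign(
            tf_name="T4", motif_id="T4", site_seq="TTTT",
            repeats=2, spacer_seqs=["TTT"],  # spacer extends the T run
            core_promoter_seq="G" * 40, core_promoter_name="core",
        )
        intended, unintended, _ = validate_design(d, lib)
        assert intended == 2
        assert unintended > 0  # shifted windows inside the TTTTTTTTTTT run


def test_spacer_length_on_genbank_output(tmp_path, library8):
    """The paper-facing constants measured on the emitted file: every spacer
    feature is 3 bp and total binding-site footprint is within half a site
    of 120 bp."""
    from synprom.formats import read_genbank_features, write_genbank

    d = build_promoter(library8[0], list(library8))
    out = tmp_path / "d.gb"
    write_genbank(d, out)
    feats = read_genbank_features(out)
    spacer_lens = {e - s for t, s, e, _, _ in feats if t == "misc_feature"}
    assert spacer_lens == {3}
    site_bp = sum(e - s for t, s, e, _, _ in feats if t == "misc_binding")
    assert abs(site_bp - 120) <= len(d.site_seq) / 2
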