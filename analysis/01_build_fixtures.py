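"""Write the composition fixture set (profiles, patterns, expected tables).

All downstream stages read these interchange files, so this step also
demonstrates that the embedded constants round-trip through the CSV/JSON
readers.
"""

from pathlib import Path

from seedqual import read_fa_profile
from seedqual.synthetic import make_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    fixtures = make_fixtures(OUT)
    print(f"fixture set written to {OUT}")
    for variety, path in fixtures.fa_profiles.items():
        profile = read_fa_profile(path)
        print(
            f"  {variety}: {len(profile)} fatty acids, "
            f"shares sum to {profile.total_pct:.2f} %, "
            f"total fat {profile.total_fat_pct_dm:.2f} % DM"
        )


if __name__ == "__main__":
    main()
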