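"""QC of the packaged UPLC-HRMS compound-characterization table.

Recomputes, for each of the 150 characterized compounds, the theoretical
adduct m/z from the molecular formula and the ppm mass error from the
printed m/z pair, and reports rows whose printed values drift from their
own inputs.
"""

from gmpnet.chem import (
    adduct_mz,
    nfpx_compound_table_path,
    parse_formula,
    read_compound_table,
    round_half_away,
    validate_compound_table,
)

records = read_compound_table(nfpx_compound_table_path())
print(f"parsed {len(records)} compound records")

adenosine = records[0]
mz = adduct_mz(adenosine.formula, adenosine.adduct)
print(
    f"{adenosine.name}: formula {adenosine.formula}, {adenosine.adduct} "
    f"theoretical m/z {round_half_away(mz, 4)} (printed {adenosine.expected_mz})"
)

report = validate_compound_table(records, tol_ppm=0.15, tol_mz=0.0005)
n_ppm = int(report["ppm_flag"].sum())
n_mz = int(report["mz_flag"].sum())
print(f"{n_ppm} rows with inconsistent printed ppm, {n_mz} with inconsistent m/z")
print("flagged rows keep their printed values; QC never overwrites them")
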