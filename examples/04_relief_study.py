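"""Run the full seven-scenario relief comparison.

Executes the no-relief baseline, selective relief at each borderline
(0.04-0.14 MPa, regions always selected from the baseline stress field),
and the conventional 10 mm mid-palatal strip, then prints the
stress-distribution volume ratio table with no-relief = 100%.  Values far
above 100 at high thresholds mean that the relief concentrated load on
the remaining support area; values near 100 mean little change.
"""

import warnings

import palate_relief as pr

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # aggressive scenarios close the gap
    report = pr.run_study(pr.StudyConfig())

print(f"baseline peak mucosal von Mises: "
      f"{report.provenance['max_von_mises_no_relief_mpa']:.3f} MPa")
print("\nvolume ratios vs no-relief (percent; NaN = zero baseline volume):")
print(report.ratios.round(1).to_string())

print("\nrelieved interface footprint per scenario (mm^2):")
for name, res in report.scenarios.items():
    print(f"  {name:18s} {res.relieved_footprint_area:8.1f}")

files = pr.render_report(report, "study_out")
print(f"\nwrote {len(files)} files to study_out/ "
      "(ratios.csv, distributions.csv, 7 VTU maps, plot)")
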