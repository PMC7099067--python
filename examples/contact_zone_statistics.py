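"""Comparative statistics over the packaged contact-zone table.

Ten secondary contacts between Western-Palearctic tree-frog lineages are
classified by how much they admix (no gene flow < steep transition < wide
transition).  The suite asks whether that ordered outcome is predicted by
(a) the divergence time of the pair and (b) whether the contact formed
before or after the Last Glacial Maximum.
"""

from clinekit import load_contact_zone_fixture, run_comparative_suite

records = load_contact_zone_fixture()
report = run_comparative_suite(records)

print(f"{len(records)} contacts loaded")
d = report.to_dict()
print(
    f"transition ~ divergence:   LR chi2 = {d['ordinal_divergence']['lr_statistic']:.2f}, "
    f"df = 1, P = {d['ordinal_divergence']['p_value']:.3f}"
)
print(
    f"transition ~ contact age:  LR chi2 = {d['ordinal_contact_age']['lr_statistic']:.2f}, "
    f"df = 1, P = {d['ordinal_contact_age']['p_value']:.3f}"
)
print(
    f"wide/steep x post/pre-LGM: chi2 = {d['chi2_wide_steep']['statistic']:.2f} (Yates), "
    f"n = {d['chi2_wide_steep']['n']}, P = {d['chi2_wide_steep']['p_value']:.3f}"
)
print(
    f"divergence, steep vs wide: W = {d['mann_whitney_divergence']['W']}, "
    f"P = {d['mann_whitney_divergence']['p_value']:.2f}"
)
print()
print("Interpretation: older pairs admix less (divergence effect), and")
print("post-glacial/introduced contacts are the wide ones, while the steep")
print("transitions sit in glacial refugia — even though the two groups do")
print("not differ in divergence time (the Mann-Whitney test).")
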