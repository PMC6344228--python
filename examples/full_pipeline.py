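"""The full pipeline: structures + biophysics in, report bundles out.

Writes four synthetic state structures and three biophysics CSVs, builds
a YAML run config, and runs both reports. The structural report ranks the
states by inter-lobe contacts; the affinity report carries the fitted Kd,
the thermodynamic signature and the DSF shift.
"""

import json
import tempfile
from pathlib import Path

import yaml

from kinland import gen_itc, gen_melt, gen_toy_kinase, run, write_pdb
from kinland.io import write_itc_csv, write_table_csv

workdir = Path(tempfile.mkdtemp(prefix="kinland_example_"))

structures = []
for label, total in [("cyclin_free_CDK1", 104), ("CDK1_cyclin_B", 133),
                     ("cyclin_free_CDK2", 141), ("CDK2_cyclin_A", 145)]:
    model, _, _ = gen_toy_kinase(contacts=total, atoms_per_lobe=1000,
                                 identifier=label)
    write_pdb(model, workdir / f"{label}.pdb")
    structures.append({
        "path": str(workdir / f"{label}.pdb"), "kinase": "TOY",
        "label": label,
        "state": "cyclin_free" if "free" in label else "cyclin_bound",
    })

iso, _ = gen_itc(kd_M=26e-9, dh_kcal=-10.4)
write_itc_csv(iso, workdir / "azd5438_cdk2_itc.csv")
for name, tm in [("apo_cdk2_dsf.csv", 51.5), ("azd5438_cdk2_dsf.csv", 60.4)]:
    curve, _ = gen_melt(tm_C=tm)
    write_table_csv(curve, workdir / name)

config = {
    "structures": structures,
    "biophysics": [
        {"path": str(workdir / "azd5438_cdk2_itc.csv"), "model": "itc",
         "inhibitor": "AZD5438", "state": "CDK2"},
        {"path": str(workdir / "apo_cdk2_dsf.csv"), "model": "dsf",
         "inhibitor": "none", "state": "CDK2", "apo": True},
        {"path": str(workdir / "azd5438_cdk2_dsf.csv"), "model": "dsf",
         "inhibitor": "AZD5438", "state": "CDK2"},
    ],
    "output_dir": str(workdir / "out"),
}
yaml.safe_dump(config, (workdir / "run.yaml").open("w"))

written = run(workdir / "run.yaml")
structural = json.loads(written["structural_json"].read_text())
affinity = json.loads(written["affinity_json"].read_text())

print("contact ranking (fewest first):")
for row in structural["ranking"]:
    flag = "  <- minimum" if row["is_minimum"] else ""
    print(f"  {row['state']:>18}: {row['total_contacts']}{flag}")
itc = [f for f in affinity["fits"] if f["model"] == "itc"][0]
print(f"AZD5438/CDK2 fitted Kd: {itc['params']['kd_M'][0] * 1e9:.1f} nM")
print(f"thermal shift: {affinity['delta_tm'][0]['delta_tm_C']:+.2f} C")
print(f"reports in: {workdir / 'out'}")
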