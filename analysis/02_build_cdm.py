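"""Validate each region against the common data model and pool the
per-region analytical datasets.

Writes one validation report per region (JSON) and the pooled minimal
event-level dataset (CSV per table). Regional person identifiers are
namespaced (region::id) so pooling can never collide.
"""

from common import build_study, outdir, parse_args


def main() -> None:
    args = parse_args(__doc__)
    study = build_study(args.seed, args.n)
    out = outdir("cdm")

    for region, report in study["validation"].items():
        report.to_json(out / f"validation_{region}.json")
        status = "pass" if report.passed else f"{len(report.violations)} violations"
        print(f"{region:10s} {status}; rows: {report.row_counts}")

    pooled = study["pooled"]
    pooled.write(out / "pooled")
    print(f"pooled dataset: {len(pooled.persons)} persons, "
          f"{len(pooled.dispensings)} relevant dispensings, "
          f"{len(pooled.hospitalizations)} hospitalizations "
          f"-> {out / 'pooled'}")


if __name__ == "__main__":
    main()
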