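# File formats

## Coordinate files

PDB (angstrom) and GRO (nanometre) files are written and read through
MDAnalysis' fixed-column writers/parsers:

- **PDB**: `ATOM` records, coordinates in Å with 3 decimals (columns
  31–54), atom name (13–16), residue name (18–21), residue id (23–26).
- **GRO**: residue id (cols 1–5), residue name (6–10), atom name
  (11–15), atom number (16–20), x/y/z in nm with 3 decimals (8.3f).
  Round-tripping is exact to the format precision (0.001 nm).

## Topology files (`.top`)

Plain-text, GROMACS-flavoured sections; `;` starts a comment.

```
[ atoms ]
; id type resid resname name charge
       0        LIG       0    GAL     O5    -0.3000
...
[ bonds ]
       0        1
[ angles ]
       0        1        2
[ dihedrals ]
       0        1        2        3
```

- `[ atoms ]`: atom id, type label, residue id, residue name, atom name,
  partial charge (e, 4 decimals).
- `[ bonds ]`: unordered pairs, smaller id first.
- `[ angles ]`: central atom in the middle, smaller endpoint first.
- `[ dihedrals ]`: path a–b–c–d along the central bond b–c, oriented so
  (a,b,c,d) ≤ (d,c,b,a) lexicographically.

Atom ids refer to the ids in the coordinate files' writing order. No
force-field parameters are included (types and charges only).

## Graft-site sidecar (`sites.tsv`)

Tab-separated: atom id of the grafting Fe and the outward unit surface
normal.

```
# atom_id	nx	ny	nz
1521	0.000000	0.000000	1.000000
```

## Template fixtures (`data/*.json`)

One JSON per residue template: `atoms` (name, element, xyz in a local
frame in Å, charge), `bonds` (name pairs), `upstream_link` /
`upstream_delete` / `downstream` link bookkeeping, `formal_charge`,
`version`. `data/manifest.json` lists every packaged file with its
sha256. The DPPC file adds a `groups` manifest naming the phosphate and
choline atoms used by the analysis selections.

## Build report (`report.json`)

The resolved config plus per-stage measurements (atom counts, realized
chain length and grafting density, topology sizes, net charge, assembled
totals, realized NP–membrane gap).
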