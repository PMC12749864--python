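# File formats

All formats are plain text. Floats are written with 6 decimals unless
noted; comment headers start with `#`.

## Extended XYZ trajectory (`.xyz`)

Per frame:

    <n_atoms>
    time_ns=<t> box=<Lx> <Ly> <Lz> [seed=<s>]
    <species> <x> <y> <z>
    ...

`seed` appears on the first frame's comment when known. The particle
list (count and species order) must be identical in every frame; frame
times must be strictly increasing. Charges are assigned from species on
read (NA/K +1, CL −1, else 0).

## Trajectory TSV (`.tsv`)

    # box = <Lx> <Ly> <Lz>
    # seed = <s>            (optional)
    frame	time_ns	particle_id	species	x	y	z
    0	0.000000	0	NA	...

One row per particle per frame; every frame must contain every particle
exactly once. The box is constant (one header line).

## Umbrella window samples

    # center = <c>
    # force_constant = <k>
    # seed = <s>
    # window_index = <w>
    time_ns	z

## WHAM metadata

One window per line, the widespread layout:

    <samples_path> <center> <force_constant>

Relative paths resolve against the metadata file's directory.

## PMF TSV

    # bin_width = <w>
    # temperature = <T>
    z	free_energy_kcal_mol	n_samples

Empty (gap) bins carry `nan` free energy.

## Pore profile TSV

    z	radius_mean	radius_sd	n

## Events TSV

    ion_id	t_enter_ns	t_exit_ns	direction

`direction` is `inward` or `outward`.

## Density

* OpenDX-style scalar grid (`write_density_dx`): `gridpositions` /
  `gridconnections` / `array` objects, C-order values, origin at the
  first voxel centre.
* Voxel-list TSV (`write_density_tsv`): `x y z density` rows (voxel
  centres), optionally thresholded.

## vdW radius table

Two whitespace-separated columns, `element radius_Å`; `#` comments
allowed. Overrides the built-in table in `read_structure` and the
`pore` CLI verb.

## PDB

Read-only, ATOM/HETATM records via biotite; occupancy/altLoc are
ignored with a logged warning, unknown elements get the 1.70 Å default
radius.
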