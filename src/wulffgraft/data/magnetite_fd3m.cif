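# Magnetite (Fe3O4) conventional unit cell, inverse spinel.
# Synthetic fixture modelled on the Crystallography Open Database magnetite
# entry (COD 1011032), re-expressed in the Fd-3m origin choice 2 setting
# (origin at the centre of symmetry):
#   Fe(tet)  8a  (1/8, 1/8, 1/8)
#   Fe(oct) 16d  (1/2, 1/2, 1/2)
#   O       32e  (u, u, u), u = 0.2549
# Full cell: 24 Fe + 32 O (Z = 8 formula units of Fe3O4).
data_magnetite_fixture
_chemical_formula_sum 'Fe24 O32'
_cell_length_a 8.3958
_cell_length_b 8.3958
_cell_length_c 8.3958
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'F d -3 m :2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
FeT Fe 0.125 0.125 0.125
FeO Fe 0.5 0.5 0.5
O1 O 0.2549 0.2549 0.2549
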