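# fretassist RMP restraints
# generated from conformer: theta=90
# NOTE: pseudoatoms must not interact with protein or solvent atoms (exclude them from nonbonded interactions in the MD topology)
# NOTE: regenerate pseudoatoms and restraints from a fresh snapshot every ~2 ns of simulation to track local backbone changes
 &rst iat=83,5, r1=0.000, r2=9.633, r3=9.633, r4=19.633, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,6, r1=1.027, r2=11.027, r3=11.027, r4=21.027, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,7, r1=0.000, r2=7.872, r3=7.872, r4=17.872, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,8, r1=0.000, r2=8.655, r3=8.655, r4=18.655, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,9, r1=0.000, r2=4.694, r3=4.694, r4=14.694, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,10, r1=0.000, r2=3.195, r3=3.195, r4=13.195, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,11, r1=0.000, r2=7.881, r3=7.881, r4=17.881, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,12, r1=0.000, r2=8.647, r3=8.647, r4=18.647, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,13, r1=0.000, r2=9.699, r3=9.699, r4=19.699, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,14, r1=1.090, r2=11.090, r3=11.090, r4=21.090, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,61, r1=0.000, r2=9.693, r3=9.693, r4=19.693, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,62, r1=1.088, r2=11.088, r3=11.088, r4=21.088, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,63, r1=0.000, r2=7.891, r3=7.891, r4=17.891, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,64, r1=0.000, r2=8.659, r3=8.659, r4=18.659, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,65, r1=0.000, r2=4.719, r3=4.719, r4=14.719, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,66, r1=0.000, r2=3.219, r3=3.219, r4=13.219, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,67, r1=0.000, r2=7.910, r3=7.910, r4=17.910, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,68, r1=0.000, r2=8.687, r3=8.687, r4=18.687, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,69, r1=0.000, r2=9.687, r3=9.687, r4=19.687, rk2=2.720448, rk3=2.720448, /
 &rst iat=84,70, r1=1.079, r2=11.079, r3=11.079, r4=21.079, rk2=2.720448, rk3=2.720448, /
 &rst iat=83,84, r1=26.978, r2=29.624, r3=32.269, r4=34.914, rk2=0.136022, rk3=0.136022, /
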