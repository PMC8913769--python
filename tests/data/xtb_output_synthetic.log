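      -----------------------------------------------------------
     |        SYNTHETIC ENGINE LOG -- hand-written test fixture   |
     |  mimics the stdout layout of a tight-binding ALPB run;     |
     |  the numbers are invented, not produced by any engine      |
      -----------------------------------------------------------

         #    Occupation            Energy/Eh            Energy/eV
      -------------------------------------------------------------
        60        2.0000           -0.4123456             -11.2205
        61        2.0000           -0.3850290             -10.4772 (HOMO)
        62                          -0.0130198              -0.3542 (LUMO)
        63                           0.0221000               0.6014
      -------------------------------------------------------------

         :::::::::::::::::::::::::::::::::::::::::::::::::::::
         ::                     SUMMARY                     ::
         :::::::::::::::::::::::::::::::::::::::::::::::::::::
         :: total energy             -40.123456789012 Eh    ::
         :: total free energy        -40.120000000000 Eh    ::
         :: gradient norm              0.000123456789 Eh/a0 ::
         :: HOMO-LUMO gap             10.123000000000 eV    ::
         ::.................................................::
         :: SCC energy               -40.567890123456 Eh    ::
         :: -> isotropic ES            0.123456789012 Eh    ::
         :: -> anisotropic ES         -0.001234567890 Eh    ::
         :: -> anisotropic XC          0.012345678901 Eh    ::
         :: -> isotropic XC           -0.034567890123 Eh    ::
         :: -> dispersion             -0.015678901234 Eh    ::
         :: -> Gsolv                  -0.010000000000 Eh    ::
         ::    -> Gelec               -0.008000000000 Eh    ::
         ::    -> Gsasa               -0.001000000000 Eh    ::
         ::    -> Ghb                 -0.001500000000 Eh    ::
         ::    -> Gshift               0.000500000000 Eh    ::
         :: repulsion energy           0.098765432109 Eh    ::
         :: atomisation energy         1.234567890123 Eh    ::
         :::::::::::::::::::::::::::::::::::::::::::::::::::::
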