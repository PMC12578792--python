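# Molar extinction coefficients of oxy- and deoxy-hemoglobin, cm^-1 / (mol/L),
# standard compiled in-vitro values (Gratzer/Kollias lineage), 10 nm spacing.
# Values at intermediate wavelengths are obtained by linear interpolation.
wavelength_nm	eps_hbo	eps_hbr
700	290.0	1794.28
710	314.0	1540.48
720	348.0	1244.84
730	390.0	1102.20
740	446.0	1115.88
750	518.0	1405.24
760	586.0	1548.52
770	650.0	1311.88
780	710.0	1075.44
790	774.0	898.68
800	816.0	761.72
810	864.0	717.08
820	916.0	693.04
830	974.0	693.04
840	1022.0	692.36
850	1058.0	691.32
860	1103.0	726.44
870	1136.0	743.60
880	1154.0	761.84
890	1178.0	794.28
900	1198.0	808.64
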