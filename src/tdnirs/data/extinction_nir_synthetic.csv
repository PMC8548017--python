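# Synthetic NIR extinction table (constructed stand-in, not a published dataset).
# Smooth spectra interpolated through widely known landmark values of oxy-/deoxy-
# hemoglobin (deoxy-Hb 760 nm band, ~800 nm isosbestic point) and pure water.
# Units: eps_hbo2, eps_hb in 1/(cm uM), natural-log (ln) convention;
# mua_water in 1/cm at unit volume fraction. Grid: 660-900 nm, 2 nm steps.
wavelength_nm,eps_hbo2,eps_hb,mua_water
660.0,7.368272e-04,7.430442e-03,1.900000e-03
662.0,7.772491e-04,7.219765e-03,1.917020e-03
664.0,8.125362e-04,7.013390e-03,1.947562e-03
666.0,8.428958e-04,6.811526e-03,1.990847e-03
668.0,8.685351e-04,6.614382e-03,2.046244e-03
670.0,8.896613e-04,6.422167e-03,2.113198e-03
672.0,9.064817e-04,6.235089e-03,2.191174e-03
674.0,9.192035e-04,6.053357e-03,2.279596e-03
676.0,9.280339e-04,5.877179e-03,2.377793e-03
678.0,9.331802e-04,5.706765e-03,2.484938e-03
680.0,9.348495e-04,5.542322e-03,2.600000e-03
682.0,9.273708e-04,5.381028e-03,2.743659e-03
684.0,9.070712e-04,5.220787e-03,2.937200e-03
686.0,8.771560e-04,5.062902e-03,3.180689e-03
688.0,8.408304e-04,4.908676e-03,3.474007e-03
690.0,8.012996e-04,4.759413e-03,3.815923e-03
692.0,7.617688e-04,4.616416e-03,4.203060e-03
694.0,7.254432e-04,4.480987e-03,4.628775e-03
696.0,6.955281e-04,4.354429e-03,5.082049e-03
698.0,6.752285e-04,4.238046e-03,5.546530e-03
700.0,6.677497e-04,4.133140e-03,6.000000e-03
702.0,6.733354e-04,4.038229e-03,6.440678e-03
704.0,6.887152e-04,3.950274e-03,6.886455e-03
706.0,7.118233e-04,3.868243e-03,7.341365e-03
708.0,7.405936e-04,3.791106e-03,7.811022e-03
710.0,7.729601e-04,3.717830e-03,8.302751e-03
712.0,8.068570e-04,3.647385e-03,8.825765e-03
714.0,8.402183e-04,3.578739e-03,9.391437e-03
716.0,8.709780e-04,3.510862e-03,1.001369e-02
718.0,8.970701e-04,3.442722e-03,1.070956e-02
720.0,9.164289e-04,3.373287e-03,1.150000e-02
722.0,9.304377e-04,3.297868e-03,1.249860e-02
724.0,9.422441e-04,3.214894e-03,1.379751e-02
726.0,9.524275e-04,3.128015e-03,1.538237e-02
728.0,9.615676e-04,3.040879e-03,1.722012e-02
730.0,9.702438e-04,2.957137e-03,1.924630e-02
732.0,9.790358e-04,2.880437e-03,2.135325e-02
734.0,9.885231e-04,2.814430e-03,2.338265e-02
736.0,9.992854e-04,2.762763e-03,2.512718e-02
738.0,1.011902e-03,2.729087e-03,2.634642e-02
740.0,1.026953e-03,2.717050e-03,2.680000e-02
742.0,1.046587e-03,2.740776e-03,2.678003e-02
744.0,1.071858e-03,2.805175e-03,2.672361e-02
746.0,1.101703e-03,2.900078e-03,2.663608e-02
748.0,1.135057e-03,3.015318e-03,2.652284e-02
750.0,1.170857e-03,3.140726e-03,2.638926e-02
752.0,1.208039e-03,3.266134e-03,2.624068e-02
754.0,1.245540e-03,3.381374e-03,2.608238e-02
756.0,1.282295e-03,3.476277e-03,2.591950e-02
758.0,1.317241e-03,3.540676e-03,2.575707e-02
760.0,1.349315e-03,3.564402e-03,2.560000e-02
762.0,1.379470e-03,3.541713e-03,2.543261e-02
764.0,1.409349e-03,3.478890e-03,2.524015e-02
766.0,1.438922e-03,3.383799e-03,2.502876e-02
768.0,1.468160e-03,3.264303e-03,2.480444e-02
770.0,1.497031e-03,3.128268e-03,2.457303e-02
772.0,1.525506e-03,2.983558e-03,2.434017e-02
774.0,1.553554e-03,2.838040e-03,2.411130e-02
776.0,1.581145e-03,2.699577e-03,2.389164e-02
778.0,1.608249e-03,2.576035e-03,2.368625e-02
780.0,1.634835e-03,2.475279e-03,2.350000e-02
782.0,1.660854e-03,2.387181e-03,2.331551e-02
784.0,1.686323e-03,2.297627e-03,2.311783e-02
786.0,1.711313e-03,2.208498e-03,2.291523e-02
788.0,1.735898e-03,2.121676e-03,2.271566e-02
790.0,1.760149e-03,2.039042e-03,2.252686e-02
792.0,1.784137e-03,1.962479e-03,2.235628e-02
794.0,1.807936e-03,1.893869e-03,2.221118e-02
796.0,1.831616e-03,1.835092e-03,2.209868e-02
798.0,1.855250e-03,1.788032e-03,2.202589e-02
800.0,1.878909e-03,1.754570e-03,2.200000e-02
802.0,1.902418e-03,1.729032e-03,2.211111e-02
804.0,1.925605e-03,1.704720e-03,2.242340e-02
806.0,1.948550e-03,1.681979e-03,2.290796e-02
808.0,1.971335e-03,1.661153e-03,2.353727e-02
810.0,1.994039e-03,1.642586e-03,2.428295e-02
812.0,2.016743e-03,1.626622e-03,2.511385e-02
814.0,2.039527e-03,1.613606e-03,2.599458e-02
816.0,2.062472e-03,1.603883e-03,2.688442e-02
818.0,2.085659e-03,1.597797e-03,2.773688e-02
820.0,2.109168e-03,1.595691e-03,2.850000e-02
822.0,2.133449e-03,1.595691e-03,2.919790e-02
824.0,2.158670e-03,1.595691e-03,2.989427e-02
826.0,2.184490e-03,1.595691e-03,3.059320e-02
828.0,2.210567e-03,1.595691e-03,3.129926e-02
830.0,2.236557e-03,1.595691e-03,3.201746e-02
832.0,2.262119e-03,1.595691e-03,3.275326e-02
834.0,2.286911e-03,1.595691e-03,3.351264e-02
836.0,2.310590e-03,1.595691e-03,3.430207e-02
838.0,2.332814e-03,1.595691e-03,3.512863e-02
840.0,2.353242e-03,1.595691e-03,3.600000e-02
842.0,2.372118e-03,1.597115e-03,3.693845e-02
844.0,2.390011e-03,1.601091e-03,3.795335e-02
846.0,2.407058e-03,1.607176e-03,3.903258e-02
848.0,2.423400e-03,1.614929e-03,4.016247e-02
850.0,2.439175e-03,1.623907e-03,4.132758e-02
852.0,2.454522e-03,1.633666e-03,4.251052e-02
854.0,2.469582e-03,1.643766e-03,4.369181e-02
856.0,2.484492e-03,1.653762e-03,4.484987e-02
858.0,2.499393e-03,1.663213e-03,4.596109e-02
860.0,2.514423e-03,1.671677e-03,4.700000e-02
862.0,2.529618e-03,1.680269e-03,4.796750e-02
864.0,2.544858e-03,1.690070e-03,4.888845e-02
866.0,2.560050e-03,1.700583e-03,4.977295e-02
868.0,2.575100e-03,1.711308e-03,5.063215e-02
870.0,2.589915e-03,1.721750e-03,5.147816e-02
872.0,2.604401e-03,1.731409e-03,5.232404e-02
874.0,2.618464e-03,1.739788e-03,5.318375e-02
876.0,2.632011e-03,1.746389e-03,5.407221e-02
878.0,2.644949e-03,1.750715e-03,5.500529e-02
880.0,2.657183e-03,1.752267e-03,5.600000e-02
882.0,2.668895e-03,1.752267e-03,5.704698e-02
884.0,2.680311e-03,1.752267e-03,5.812550e-02
886.0,2.691412e-03,1.752267e-03,5.923645e-02
888.0,2.702176e-03,1.752267e-03,6.038072e-02
890.0,2.712581e-03,1.752267e-03,6.155924e-02
892.0,2.722607e-03,1.752267e-03,6.277296e-02
894.0,2.732233e-03,1.752267e-03,6.402287e-02
896.0,2.741437e-03,1.752267e-03,6.530998e-02
898.0,2.750199e-03,1.752267e-03,6.663533e-02
900.0,2.758497e-03,1.752267e-03,6.800000e-02
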